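"""GLM fitting, stepwise simplification, peaks and delays."""

import numpy as np
import pandas as pd
import pytest

from anthonet import (
    ModelSpec,
    PlantSurveyRecord,
    aggregate_observations,
    dispersion_check,
    fit_glm,
    alpine_campaign_config,
    peak_delay,
    plant_model_spec,
    predict_curve,
    select_focal_families,
    simulate_dataset,
    stepwise_simplify,
    visitor_model_spec,
)
from anthonet.phenology import (
    FitResult,
    aggregate_plant_observations,
    droppable_terms,
    term_name,
)


def _table(jd, elev, response, group=None, **extra):
    df = pd.DataFrame({"julian_day": jd, "elevation": elev,
                       "response": response})
    if group is not None:
        df["group"] = group
    for k, v in extra.items():
        df[k] = v
    return df


class TestAggregateObservations:
    def test_abundance_and_richness(self, make_record):
        records = [make_record(species="a", count=1),
                   make_record(species="a", count=1),
                   make_record(species="b", count=1)]
        ab = aggregate_observations(records, "order", "abundance")
        ri = aggregate_observations(records, "order", "richness")
        assert ab.loc[0, "response"] == 3 and ri.loc[0, "response"] == 2

    def test_sampled_day_without_group_gets_zero_row(self, make_record):
        records = [make_record(order="Diptera", jd=160),
                   make_record(order="Hymenoptera", jd=167)]
        table = aggregate_observations(records, "order", "abundance")
        zero = table[(table.group == "Diptera") & (table.julian_day == 167)]
        assert len(zero) == 1 and zero.iloc[0].response == 0
        assert len(table) == 4  # 2 days x 2 groups

    def test_matches_generator_tallies(self):
        records, _ = simulate_dataset(alpine_campaign_config(seed=3))
        table = aggregate_observations(records, "family", "abundance")
        tally: dict = {}
        for r in records:
            key = (r.site_id, r.julian_day, r.family)
            tally[key] = tally.get(key, 0) + r.count
        for _, row in table.iterrows():
            key = (row.site_id, row.julian_day, row.group)
            assert row.response == tally.get(key, 0)

    def test_unknown_level_is_error(self, make_record):
        with pytest.raises(ValueError):
            aggregate_observations([make_record()], "genus")

    def test_plant_survey_aggregation(self):
        surveys = [PlantSurveyRecord("S01", 160, "P1", 4),
                   PlantSurveyRecord("S01", 160, "P2", 0),
                   PlantSurveyRecord("S01", 167, "P1", 2)]
        ab = aggregate_plant_observations(surveys, {"S01": 1200.0}, "abundance")
        ri = aggregate_plant_observations(surveys, {"S01": 1200.0}, "richness")
        assert list(ab.response) == [4, 2]
        assert list(ri.response) == [1, 1]  # zero-abundance plant not counted


class TestSelectFocalFamilies:
    def _records(self, shares, make, total=100):
        records = []
        for i, share in enumerate(shares):
            records.append(make(family=f"F{i}", species=f"F{i}_sp",
                                count=int(share * total)))
        return records

    def test_cumulative_share_rule(self, make_record):
        assert select_focal_families(
            self._records([0.50, 0.30, 0.20], make_record), "Diptera") == \
            ["F0", "F1"]

    def test_single_family_alone(self, make_record):
        assert select_focal_families(
            self._records([1.0], make_record), "Diptera") == ["F0"]

    def test_just_below_threshold_extends_prefix(self, make_record):
        assert select_focal_families(
            self._records([0.74, 0.26], make_record), "Diptera") == ["F0", "F1"]

    def test_absent_order_is_error(self, make_record):
        with pytest.raises(ValueError):
            select_focal_families([make_record()], "Coleoptera")


class TestFitGLM:
    def test_intercept_only_is_log_mean(self):
        table = _table([160, 167, 174], [1000] * 3, [1, 2, 3])
        fit = fit_glm(table, ModelSpec("response", ()))
        assert fit.params["Intercept"] == pytest.approx(np.log(2), abs=1e-8)

    def test_exact_log_linear_recovery(self):
        x = np.array([0.0, 1.0, 2.0])
        table = _table([160] * 3, [1000] * 3, np.exp(1 + 0.5 * x), x=x)
        fit = fit_glm(table, ModelSpec("response", (("x",),)))
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["x"] == pytest.approx(0.5, abs=1e-6)

    def test_negative_response_rejected(self):
        table = _table([160, 167], [1000, 1000], [1, -1])
        with pytest.raises(ValueError, match="non-negative"):
            fit_glm(table, ModelSpec("response", ()))

    def test_rank_deficiency_names_aliased_terms(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        table = _table([160] * 4, [1000] * 4, [1, 2, 3, 4], x=x, y=2 * x)
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(table, ModelSpec("response", (("x",), ("y",))))

    def test_quasi_poisson_same_estimates_scaled_errors(self):
        rng = np.random.default_rng(0)
        table = _table(rng.integers(150, 200, 60), rng.uniform(1000, 2500, 60),
                       rng.poisson(5.0, 60))
        spec = plant_model_spec()
        pois = fit_glm(table, spec)
        quasi = fit_glm(table, spec.with_family("quasipoisson"))
        assert np.allclose(pois.params, quasi.params)
        assert np.allclose(quasi.bse, pois.bse * np.sqrt(pois.dispersion))

    def test_coding_invariance_of_fitted_values(self):
        """External rescaling of elevation must not move the fit."""
        rng = np.random.default_rng(1)
        jd = rng.integers(150, 200, 80)
        elev = rng.uniform(1000, 2500, 80)
        y = rng.poisson(4.0, 80)
        spec = plant_model_spec()
        fit_m = fit_glm(_table(jd, elev, y), spec)
        fit_km = fit_glm(_table(jd, elev / 1000.0, y), spec)
        assert fit_m.deviance == pytest.approx(fit_km.deviance, abs=1e-8)
        assert np.allclose(fit_m.results.fittedvalues,
                           fit_km.results.fittedvalues, atol=1e-8)


class TestDispersion:
    def _fit_like(self, dispersion, df_resid=10):
        return FitResult(spec=ModelSpec("response", ()), params=pd.Series(),
                         bse=pd.Series(), deviance=0.0, df_resid=df_resid,
                         pearson_chi2=dispersion * df_resid,
                         dispersion=dispersion, n_obs=df_resid + 1, coding={},
                         jd_range=(0, 1), elev_range=(0, 1), groups=())

    def test_perfect_fit_keeps_poisson(self):
        table = _table([160, 167], [1000, 1000], [2, 2])
        fit = fit_glm(table, ModelSpec("response", ()))
        assert fit.dispersion == pytest.approx(0.0, abs=1e-10)
        assert dispersion_check(fit) == "poisson"

    def test_threshold_is_strict(self):
        assert dispersion_check(self._fit_like(1.5)) == "poisson"
        assert dispersion_check(self._fit_like(1.5 + 1e-9)) == "quasipoisson"

    def test_zero_residual_df_is_error(self):
        with pytest.raises(ValueError):
            dispersion_check(self._fit_like(1.0, df_resid=0))

    def test_overdispersed_counts_flagged(self):
        """Gamma-Poisson mixture with variance 3x the mean."""
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mu = 8.0
            lam = rng.gamma(shape=mu / 2.0, scale=2.0, size=80)
            table = _table(rng.integers(150, 200, 80),
                           rng.uniform(1000, 2500, 80), rng.poisson(lam))
            fit = fit_glm(table, ModelSpec("response", ()))
            flagged += dispersion_check(fit) == "quasipoisson"
        assert flagged >= 95


class TestStepwise:
    def test_marginality_protects_constituents(self):
        # only the quadratic three-ways are free; group:elev:jd is their
        # lower-order relative (jd2 contains jd) and stays protected
        spec = visitor_model_spec()
        droppable = {term_name(t) for t in droppable_terms(spec)}
        assert droppable == {"group:elev:jd2", "group:elev2:jd"}
        both_dropped = spec.drop(("group", "elev", "jd2")).drop(
            ("group", "elev2", "jd"))
        assert ("group", "elev", "jd") in droppable_terms(both_dropped)
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("response", (("elev", "jd"),))

    def test_quadratic_protects_linear_part(self):
        spec = ModelSpec("response", (("jd",), ("jd2",)))
        assert [term_name(t) for t in droppable_terms(spec)] == ["jd2"]

    def test_strongly_supported_terms_all_retained(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        z = rng.normal(size=300)
        y = rng.poisson(np.exp(0.5 + 1.0 * x + 1.0 * z))
        table = _table(rng.integers(150, 200, 300),
                       rng.uniform(1000, 2500, 300), y, x=x, z=z)
        spec = ModelSpec("response", (("x",), ("z",)))
        final, _, log = stepwise_simplify(table, spec)
        assert final.terms == spec.terms
        assert (log.action == "stopped").all()

    def test_pure_noise_term_dropped(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=250)
        noise = rng.normal(size=250)
        y = rng.poisson(np.exp(0.3 + 0.9 * x))
        table = _table(rng.integers(150, 200, 250),
                       rng.uniform(1000, 2500, 250), y, x=x, noise=noise)
        final, _, log = stepwise_simplify(
            table, ModelSpec("response", (("x",), ("noise",))))
        assert ("x",) in final.terms and ("noise",) not in final.terms
        dropped = log[log.action == "dropped"]
        assert list(dropped.term) == ["noise"]

    def test_deviance_differences_nonnegative(self):
        records, _ = simulate_dataset(alpine_campaign_config(seed=2))
        table = aggregate_observations(records, "order", "abundance")
        _, _, log = stepwise_simplify(table, visitor_model_spec())
        assert (log.delta_deviance >= -1e-8).all()


class TestPredictAndPeaks:
    def test_intercept_only_flat_line(self):
        table = _table([160, 167, 174], [1000] * 3, [2, 2, 2])
        fit = fit_glm(table, ModelSpec("response", ()))
        curve = predict_curve(fit, None, 1000.0, np.array([161.0, 170.0]))
        assert np.allclose(curve, 2.0)

    def test_quadratic_peak_matches_closed_form(self):
        # log mu = 5 - (jd-172)^2/200: interior max exactly at 172
        jd = np.arange(150, 195)
        mu = np.exp(5 - (jd - 172.0) ** 2 / 200.0)
        table = _table(jd, [1000.0] * len(jd), mu)
        fit = fit_glm(table, ModelSpec("response", (("jd",), ("jd2",))))
        est = peak_delay(fit, None, [1000.0, 1000.0 + 1e-9])
        assert est.peaks.peak_day.iloc[0] == pytest.approx(172.0, abs=0.1)

    def test_fitted_totals_preserved_with_intercept(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(6.0, 50)
        table = _table(rng.integers(150, 200, 50),
                       rng.uniform(1000, 2500, 50), y)
        fit = fit_glm(table, plant_model_spec())
        assert fit.results.fittedvalues.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_extrapolation_warns(self):
        table = _table([160, 167, 174], [1000] * 3, [1, 2, 3])
        fit = fit_glm(table, ModelSpec("response", ()))
        with pytest.warns(UserWarning, match="outside"):
            predict_curve(fit, None, 1000.0, np.array([100.0]))

    def test_monotone_curve_flagged_boundary(self):
        jd = np.arange(150, 190)
        table = _table(jd, [1000.0] * len(jd), np.exp(0.05 * (jd - 150)))
        fit = fit_glm(table, ModelSpec("response", (("jd",),)))
        est = peak_delay(fit, None, [1000.0, 1200.0])
        assert est.peaks.boundary.all()
        assert np.isnan(est.delay_per_300m)

    def test_group_must_be_known(self, make_record):
        records = [make_record(order=o, jd=d, species=f"{o}{d}")
                   for o in ("Diptera", "Hymenoptera") for d in (155, 165, 175)]
        table = aggregate_observations(records, "order", "abundance")
        fit = fit_glm(table, ModelSpec("response", (("group",),)))
        with pytest.raises(ValueError, match="group"):
            predict_curve(fit, "Plecoptera", 1200.0, np.array([160.0]))
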