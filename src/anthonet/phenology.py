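"""Poisson/quasi-Poisson GLMs for abundance and richness phenology.

Counts per site x sampling day (x taxonomic group for the insect
models) are modelled on the log scale as quadratic functions of Julian
day and elevation with group interactions up to three-way, then
simplified by backward elimination: at each step the droppable term
with the highest likelihood-ratio p-value is removed as long as the
chi-square test on the deviance difference is non-significant.
Marginality is enforced throughout — a main effect (or a quadratic's
linear part) is never dropped while a term containing it remains.

Fitted curves give, per group and elevation, the Julian day of peak
abundance/richness; regressing peak day on elevation yields the
phenological delay in days per +300 m of altitude.

Julian day and elevation are centred and scaled internally before
quadratics are formed (numerical conditioning); every reported
quantity is on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .records import PlantSurveyRecord, VisitRecord

Term = tuple[str, ...]

#: Mapping of model factors to design-formula fragments over the
#: internally scaled columns.
_FACTOR_CODE = {
    "jd": "jd_s",
    "jd2": "I(jd_s**2)",
    "elev": "elev_s",
    "elev2": "I(elev_s**2)",
    "group": "C(group)",
}
_FACTOR_RANK = {"group": 0, "elev": 1, "elev2": 2, "jd": 3, "jd2": 4}


def _canon(term: Sequence[str]) -> Term:
    return tuple(sorted(term, key=lambda f: (_FACTOR_RANK.get(f, 99), f)))


def term_name(term: Term) -> str:
    return ":".join(term)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative GLM structure: response, terms, error family."""

    response: str
    terms: tuple[Term, ...]
    family: Literal["poisson", "quasipoisson"] = "poisson"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(_canon(t) for t in self.terms))
        present = set(self.terms)
        for t in self.terms:
            if len(t) > 1:
                for f in t:
                    if (f,) not in present:
                        raise ValueError(
                            f"marginality violated: interaction {term_name(t)} "
                            f"without main effect {f}")

    def drop(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.response,
                         tuple(t for t in self.terms if t != _canon(term)),
                         self.family)

    def with_family(self, family: str) -> "ModelSpec":
        return ModelSpec(self.response, self.terms, family)  # type: ignore[arg-type]

    def formula(self) -> str:
        parts = [":".join(_FACTOR_CODE.get(f, f) for f in t) for t in self.terms]
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.response} ~ {rhs}"


def plant_model_spec(response: str = "response",
                     family: str = "poisson") -> ModelSpec:
    """Bloom-survey model: quadratic JD x quadratic elevation surface."""
    terms = [("jd",), ("jd2",), ("elev",), ("elev2",),
             ("elev", "jd"), ("elev", "jd2"), ("elev2", "jd")]
    return ModelSpec(response, tuple(terms), family)  # type: ignore[arg-type]


def visitor_model_spec(response: str = "response",
                       family: str = "poisson") -> ModelSpec:
    """Insect model: plant surface + taxonomic group, interactions to 3-way."""
    terms = [("jd",), ("jd2",), ("elev",), ("elev2",), ("group",),
             ("elev", "jd"), ("elev", "jd2"), ("group", "elev"),
             ("elev2", "jd"), ("group", "elev2"), ("group", "jd"),
             ("group", "jd2"),
             ("group", "elev", "jd"), ("group", "elev", "jd2"),
             ("group", "elev2", "jd")]
    return ModelSpec(response, tuple(terms), family)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Observation tables
# ---------------------------------------------------------------------------

def aggregate_observations(
    records: Sequence[VisitRecord],
    level: Literal["order", "family"],
    response: Literal["abundance", "richness"] = "abundance",
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per (site, sampling day, group) with the count response.

    Abundance sums visit counts; richness counts distinct species-level
    names. Every (site, day, group) combination that was sampled — i.e.
    the day appears in that site's records for any group — is present,
    with response 0 when the group was not seen: the zeros are real
    design points, not missing data. At family level, records without a
    family label cannot be attributed and are left out.
    """
    if level not in ("order", "family"):
        raise ValueError(f"unknown level {level!r}")
    if not records:
        return pd.DataFrame(columns=["site_id", "elevation", "julian_day",
                                     "group", "response"])
    elev_of = {}
    sampled: set[tuple[str, int]] = set()
    for r in records:
        elev_of.setdefault(r.site_id, r.elevation)
        sampled.add((r.site_id, r.julian_day))

    rows = []
    for r in records:
        g = r.order if level == "order" else r.family
        if not g:
            continue
        rows.append((r.site_id, r.julian_day, g, r.count,
                     r.species if r.species_level else None))
    frame = pd.DataFrame(rows, columns=["site_id", "julian_day", "group",
                                        "count", "species"])
    if groups is None:
        groups = sorted(frame["group"].unique())
    frame = frame[frame["group"].isin(groups)]
    if response == "abundance":
        agg = frame.groupby(["site_id", "julian_day", "group"])["count"].sum()
    elif response == "richness":
        agg = (frame.dropna(subset=["species"])
               .groupby(["site_id", "julian_day", "group"])["species"].nunique())
    else:
        raise ValueError(f"unknown response {response!r}")

    grid = pd.MultiIndex.from_tuples(
        [(s, d, g) for (s, d) in sorted(sampled) for g in groups],
        names=["site_id", "julian_day", "group"])
    out = agg.reindex(grid, fill_value=0).reset_index(name="response")
    out.insert(1, "elevation", out["site_id"].map(elev_of))
    return out


def aggregate_plant_observations(
    surveys: Sequence[PlantSurveyRecord],
    elevations: Mapping[str, float],
    response: Literal["abundance", "richness"] = "abundance",
) -> pd.DataFrame:
    """Bloom-survey table: one row per (site, day), no group column."""
    if not surveys:
        return pd.DataFrame(columns=["site_id", "elevation", "julian_day",
                                     "response"])
    frame = pd.DataFrame(
        [(s.site_id, s.julian_day, s.plant_species, s.abundance) for s in surveys],
        columns=["site_id", "julian_day", "plant_species", "abundance"])
    if response == "abundance":
        agg = frame.groupby(["site_id", "julian_day"])["abundance"].sum()
    elif response == "richness":
        agg = (frame[frame["abundance"] > 0]
               .groupby(["site_id", "julian_day"])["plant_species"].nunique())
        agg = agg.reindex(frame.groupby(["site_id", "julian_day"]).size().index,
                          fill_value=0)
    else:
        raise ValueError(f"unknown response {response!r}")
    out = agg.reset_index(name="response")
    out.insert(1, "elevation", out["site_id"].map(dict(elevations)))
    if out["elevation"].isna().any():
        missing = sorted(out.loc[out["elevation"].isna(), "site_id"].unique())
        raise ValueError(f"no elevation given for sites {missing}")
    return out


def select_focal_families(records: Sequence[VisitRecord], order: str) -> list[str]:
    """Most-visited families jointly holding >= 75% of an order's visits.

    Families are ranked by descending visit count and the shortest
    prefix whose cumulative share reaches 0.75 of all the order's
    visits (including family-unresolved ones) is returned.
    """
    order_records = [r for r in records if r.order == order]
    if not order_records:
        raise ValueError(f"order {order!r} absent from records")
    total = sum(r.count for r in order_records)
    per_family: dict[str, int] = {}
    for r in order_records:
        if r.family:
            per_family[r.family] = per_family.get(r.family, 0) + r.count
    ranked = sorted(per_family.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen, cum = [], 0
    for fam, n in ranked:
        chosen.append(fam)
        cum += n
        if cum >= 0.75 * total:
            break
    return chosen


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted phenology GLM plus the coding needed to predict from it."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    deviance: float
    df_resid: int
    pearson_chi2: float
    dispersion: float
    n_obs: int
    coding: dict[str, float]  # jd_mean, jd_scale, elev_mean, elev_scale
    jd_range: tuple[float, float]
    elev_range: tuple[float, float]
    groups: tuple[str, ...]
    results: object = field(repr=False, default=None)  # statsmodels GLMResults

    def scaled_frame(self, jd: np.ndarray, elevation: float,
                     group: str | None) -> pd.DataFrame:
        c = self.coding
        df = pd.DataFrame({
            "jd_s": (np.asarray(jd, dtype=float) - c["jd_mean"]) / c["jd_scale"],
            "elev_s": (elevation - c["elev_mean"]) / c["elev_scale"],
        })
        if group is not None:
            df["group"] = group
        return df


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    df = table.copy()
    if df.empty:
        raise ValueError("empty observation table")
    y = df[spec.response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("response must be non-negative")
    coding = {}
    for col, key in (("julian_day", "jd"), ("elevation", "elev")):
        v = df[col].to_numpy(dtype=float)
        mean = float(v.mean())
        scale = float(v.std()) or 1.0
        coding[f"{key}_mean"], coding[f"{key}_scale"] = mean, scale
        df[f"{key}_s"] = (v - mean) / scale
    return df, coding


def fit_glm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the specified Poisson-family GLM with log link.

    IRLS runs until the deviance change falls below 1e-8 (at most 100
    iterations). The quasi-Poisson family keeps the Poisson point
    estimates and multiplies standard errors by the square root of the
    Pearson dispersion.
    """
    df, coding = _prepare(table, spec)
    uses_group = any("group" in t for t in spec.terms)
    model = smf.glm(spec.formula(), data=df, family=sm.families.Poisson())
    exog = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        aliased = [model.exog_names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"design matrix rank deficient; aliased terms: {aliased}")
    res = model.fit(maxiter=100, tol=1e-8)
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])}")
    df_resid = int(res.df_resid)
    pearson = float(res.pearson_chi2)
    dispersion = pearson / df_resid if df_resid > 0 else float("nan")
    bse = res.bse.copy()
    if spec.family == "quasipoisson":
        if df_resid <= 0:
            raise ValueError("quasi-Poisson scale needs residual df > 0")
        bse = bse * np.sqrt(dispersion)
    return FitResult(
        spec=spec,
        params=res.params,
        bse=bse,
        deviance=float(res.deviance),
        df_resid=df_resid,
        pearson_chi2=pearson,
        dispersion=dispersion,
        n_obs=int(res.nobs),
        coding=coding,
        jd_range=(float(df["julian_day"].min()), float(df["julian_day"].max())),
        elev_range=(float(df["elevation"].min()), float(df["elevation"].max())),
        groups=tuple(sorted(df["group"].unique())) if uses_group else (),
        results=res,
    )


def _patsy_term_name(term: Term) -> str:
    # patsy normalizes embedded code with spaces around operators
    norm = {"jd2": "I(jd_s ** 2)", "elev2": "I(elev_s ** 2)"}
    return ":".join(norm.get(f, _FACTOR_CODE.get(f, f)) for f in term)


def prune_aliased_terms(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[ModelSpec, list[Term]]:
    """Drop terms until the design matrix has full column rank.

    Degenerate designs (a single sampling day, one site, one group
    level) make parts of the full model inestimable; the standard
    remedy is to remove the aliased terms, highest interaction order
    first and marginality-consistently, before fitting.
    """
    removed: list[Term] = []
    while spec.terms:
        df, _ = _prepare(table, spec)
        model = smf.glm(spec.formula(), data=df, family=sm.families.Poisson())
        exog = np.asarray(model.exog)
        rank = np.linalg.matrix_rank(exog)
        if rank == exog.shape[1]:
            break
        slices = model.data.design_info.term_name_slices
        # drop one droppable term whose columns contribute no rank
        for t in sorted(droppable_terms(spec),
                        key=lambda t: (-len(t), term_name(t))):
            sl = slices[_patsy_term_name(t)]
            keep = [j for j in range(exog.shape[1])
                    if not sl.start <= j < sl.stop]
            if np.linalg.matrix_rank(exog[:, keep]) == rank:
                spec = spec.drop(t)
                removed.append(t)
                break
        else:  # deficiency not resolvable by marginality-safe drops
            break
    return spec, removed


def dispersion_check(fit: FitResult, threshold: float = 1.5) -> str:
    """Recommend quasi-Poisson when Pearson chi2/df exceeds the threshold.

    The comparison is strict, so dispersion exactly at the threshold
    keeps the plain Poisson family.
    """
    if fit.df_resid <= 0:
        raise ValueError("dispersion undefined with zero residual df")
    return "quasipoisson" if fit.dispersion > threshold else "poisson"


# ---------------------------------------------------------------------------
# Stepwise simplification
# ---------------------------------------------------------------------------

def _closure(term: Term) -> set[str]:
    """Factors a term protects: its own, plus linear parts of quadratics."""
    out = set(term)
    if "jd2" in out:
        out.add("jd")
    if "elev2" in out:
        out.add("elev")
    return out


def droppable_terms(spec: ModelSpec) -> list[Term]:
    """Terms whose removal respects marginality."""
    out = []
    for t in spec.terms:
        protected = any(set(t) <= _closure(u) for u in spec.terms if u != t)
        if not protected:
            out.append(t)
    return out


def stepwise_simplify(
    table: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Backward elimination by likelihood-ratio chi-square tests.

    At each step every marginality-droppable term is tested by refitting
    without it and comparing deviances (scaled by the Pearson dispersion
    for the quasi-Poisson family); the term with the largest p-value is
    dropped while that p-value exceeds ``alpha``. Ties go to the
    highest-order interaction. Returns the simplified spec, its fit and
    the full drop log.
    """
    current = spec
    fit = fit_glm(table, current)
    log_rows = []
    step = 0
    while True:
        candidates = droppable_terms(current)
        if not candidates:
            break
        phi = 1.0
        if current.family == "quasipoisson":
            phi = max(fit.dispersion, 1e-12)
        tested = []
        for term in candidates:
            reduced_fit = fit_glm(table, current.drop(term))
            ddev = reduced_fit.deviance - fit.deviance
            ddf = reduced_fit.df_resid - fit.df_resid
            p = float(scipy.stats.chi2.sf(max(ddev, 0.0) / phi, ddf))
            tested.append((term, reduced_fit, ddev, ddf, p))
        # highest p first; ties: drop the highest-order interaction
        tested.sort(key=lambda t: (-t[4], -len(t[0]), term_name(t[0])))
        term, reduced_fit, ddev, ddf, p = tested[0]
        step += 1
        if p > alpha:
            log_rows.append({"step": step, "term": term_name(term),
                             "delta_deviance": ddev, "delta_df": ddf,
                             "p_value": p, "action": "dropped"})
            current = current.drop(term)
            fit = reduced_fit
        else:
            log_rows.append({"step": step, "term": term_name(term),
                             "delta_deviance": ddev, "delta_df": ddf,
                             "p_value": p, "action": "stopped"})
            break
    log = pd.DataFrame(log_rows, columns=["step", "term", "delta_deviance",
                                          "delta_df", "p_value", "action"])
    return current, fit, log


# ---------------------------------------------------------------------------
# Predicted curves and phenology peaks
# ---------------------------------------------------------------------------

def predict_curve(
    fit: FitResult,
    group: str | None,
    elevation: float,
    jd_grid: np.ndarray,
) -> np.ndarray:
    """Response-scale predictions over a Julian-day grid."""
    jd_grid = np.asarray(jd_grid, dtype=float)
    lo, hi = fit.jd_range
    if jd_grid.min() < lo or jd_grid.max() > hi:
        warnings.warn(
            f"predicting outside the fitted Julian-day range [{lo}, {hi}]",
            stacklevel=2)
    if fit.groups and group is None:
        raise ValueError(f"model has groups {fit.groups}; one must be chosen")
    if fit.groups and group not in fit.groups:
        raise ValueError(f"group {group!r} not among fitted groups {fit.groups}")
    newdata = fit.scaled_frame(jd_grid, elevation, group if fit.groups else None)
    return np.asarray(fit.results.predict(newdata))


@dataclass
class PeakEstimate:
    """Phenology peaks per elevation and their altitudinal delay."""

    group: str | None
    peaks: pd.DataFrame  # elevation, peak_day, peak_height, boundary
    delay_per_300m: float
    delay_ci: tuple[float, float]
    n_elevations_used: int


def _slope_from_peaks(grid: np.ndarray, pred: np.ndarray,
                      elevations: np.ndarray) -> float:
    """LS slope of interior peak day on elevation; NaN if < 2 interior."""
    idx = pred.argmax(axis=0)
    interior = (idx > 0) & (idx < grid.size - 1)
    if interior.sum() < 2 or np.unique(elevations[interior]).size < 2:
        return float("nan")
    reg = scipy.stats.linregress(elevations[interior], grid[idx[interior]])
    return float(reg.slope)


def peak_delay(
    fit: FitResult,
    group: str | None,
    elevations: Sequence[float],
    grid_step: float = 0.1,
    n_boot: int = 200,
    seed: int = 0,
) -> PeakEstimate:
    """Locate the fitted peak day at each elevation; regress on altitude.

    The peak is the argmax of the predicted curve on a 0.1-day grid over
    the observed Julian-day range. A maximum at either end of the range
    is flagged as a boundary (no interior peak) and excluded from the
    delay regression. The delay is the least-squares slope of peak day
    on elevation, reported per +300 m; its 95% confidence interval is a
    parametric bootstrap, re-deriving peaks from coefficient vectors
    drawn from the fitted model's sampling distribution (so the interval
    reflects GLM estimation uncertainty, not merely the scatter of the
    point peaks around the regression line).
    """
    import patsy

    elevations = np.asarray(list(elevations), dtype=float)
    if elevations.size < 2:
        raise ValueError("need at least two elevations")
    lo, hi = fit.jd_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    # design matrix of the full (elevation x grid) prediction frame
    frames = [fit.scaled_frame(grid, e, group if fit.groups else None)
              for e in elevations]
    newdata = pd.concat(frames, ignore_index=True)
    design_info = fit.results.model.data.design_info
    X = np.asarray(patsy.dmatrix(design_info, newdata))
    mu = np.exp(X @ np.asarray(fit.params)).reshape(elevations.size, grid.size).T

    rows = []
    for k, e in enumerate(elevations):
        i = int(np.argmax(mu[:, k]))
        rows.append({"elevation": float(e), "peak_day": float(grid[i]),
                     "peak_height": float(mu[i, k]),
                     "boundary": i == 0 or i == grid.size - 1})
    peaks = pd.DataFrame(rows)
    slope = _slope_from_peaks(grid, mu, elevations)
    slope300 = slope * 300.0

    ci = (float("nan"), float("nan"))
    if n_boot > 0 and np.isfinite(slope300):
        cov = np.asarray(fit.results.cov_params())
        if fit.spec.family == "quasipoisson":
            cov = cov * fit.dispersion
        rng = np.random.default_rng(seed)
        betas = rng.multivariate_normal(np.asarray(fit.params), cov,
                                        size=n_boot, method="svd")
        slopes = []
        for b in betas:
            mu_b = np.exp(X @ b).reshape(elevations.size, grid.size).T
            s = _slope_from_peaks(grid, mu_b, elevations)
            if np.isfinite(s):
                slopes.append(s * 300.0)
        if len(slopes) >= max(20, n_boot // 4):
            ci = (float(np.percentile(slopes, 2.5)),
                  float(np.percentile(slopes, 97.5)))
    return PeakEstimate(group=group, peaks=peaks, delay_per_300m=slope300,
                        delay_ci=ci,
                        n_elevations_used=int((~peaks["boundary"]).sum()))
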