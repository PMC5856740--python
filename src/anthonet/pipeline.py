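"""End-to-end orchestration: data -> networks -> GLMs -> overlap -> report.

A run is driven by one :class:`PipelineConfig` (exactly one of an input
CSV or a simulation scenario), executes its stages in a fixed order,
writes every artefact under one output directory, and records a
manifest with sha256 checksums so a repeated run with the same seed can
be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import network as net
from . import overlap as ov
from . import phenology as ph
from .records import VisitRecord, exclude_species, read_visits, write_visits
from .simulate import alpine_campaign_config, simulate_dataset


@dataclass
class PipelineConfig:
    """Options of one full analysis run."""

    output_dir: str
    input_path: str | None = None
    simulate: bool = False
    null_mode: bool = False
    seed: int = 0
    levels: tuple[str, ...] = ("order",)
    alpha: float = 0.05
    dispersion_threshold: float = 1.5
    B: int = 1000
    exclude_honeybee: bool = False
    visit_scale: float = 1.0

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise ValueError("exactly one of input_path or simulate must be set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be > 0")
        for level in self.levels:
            if level not in ("order", "family"):
                raise ValueError(f"unknown level {level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "levels" in data:
            data["levels"] = tuple(data["levels"])
        return cls(**data)


@dataclass
class RunReport:
    """Audit trail of one run."""

    seed: int
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: object, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every analysis stage and write all artefacts.

    Stages: load (read or simulate visits) -> networks -> composition ->
    phenology GLM with stepwise simplification and peak delays ->
    overlap suite with Jost combination -> report/manifest. Outputs are
    deterministic given the seed; no timestamps are written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config=dataclasses.asdict(config))

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - named-stage contract
                raise StageError(name, exc) from exc
        return wrap

    # --- load ---------------------------------------------------------
    def _load() -> list[VisitRecord]:
        if config.simulate:
            sim = alpine_campaign_config(seed=config.seed,
                                    visit_scale=config.visit_scale)
            records, _ = simulate_dataset(sim, null_mode=config.null_mode)
            write_visits(records, out / "visits.csv")
        else:
            result = read_visits(config.input_path)
            records = result.records
            for rej in result.rejections:
                report.warnings.append(
                    f"rejected input row {rej.row_number}: {rej.reason}")
        if config.exclude_honeybee:
            before = len(records)
            records = exclude_species(records)
            report.stage_counts["honeybee_excluded_rows"] = before - len(records)
        if not records:
            raise ValueError("no valid visit records")
        return records

    records = _stage("load")(_load)
    report.stage_counts["records"] = len(records)
    report.stage_counts["visits"] = sum(r.count for r in records)

    # --- networks -----------------------------------------------------
    def _networks():
        site_ids = sorted({r.site_id for r in records})
        networks = [net.build_network(records, s) for s in site_ids]
        net.write_edge_lists(networks, out / "edge_lists.tsv")
        return networks

    networks = _stage("networks")(_networks)
    report.stage_counts["sites"] = len(networks)

    # --- composition --------------------------------------------------
    def _composition():
        comp = net.composition_summary(records)
        comp.to_csv(out / "composition.tsv", sep="\t", index=False,
                    float_format="%.6g")
        return comp

    composition = _stage("composition")(_composition)
    report.stage_counts["orders"] = len(composition)

    # --- phenology GLM ------------------------------------------------
    def _phenology():
        peaks_doc = {}
        for level in config.levels:
            if level == "order":
                table = ph.aggregate_observations(records, "order", "abundance")
            else:
                families = ph.select_focal_families(records, "Diptera")
                diptera = [r for r in records if r.order == "Diptera"]
                table = ph.aggregate_observations(diptera, "family",
                                                  "abundance", groups=families)
            spec = ph.visitor_model_spec()
            spec, pruned = ph.prune_aliased_terms(table, spec)
            for t in pruned:
                report.warnings.append(
                    f"{level}-level model: term {ph.term_name(t)} inestimable "
                    f"on this design, removed before fitting")
            fit0 = ph.fit_glm(table, spec)
            if fit0.df_resid > 0:
                family = ph.dispersion_check(fit0, config.dispersion_threshold)
            else:
                family = "poisson"
                report.warnings.append(
                    f"{level}-level model saturated (0 residual df); "
                    f"dispersion not assessed")
            if family == "quasipoisson":
                spec = spec.with_family("quasipoisson")
                report.warnings.append(
                    f"{level}-level model overdispersed "
                    f"(phi={fit0.dispersion:.3g}); quasi-Poisson errors used")
            final_spec, fit, drop_log = ph.stepwise_simplify(
                table, spec, alpha=config.alpha)
            coef = pd.DataFrame({"term": fit.params.index,
                                 "estimate": fit.params.to_numpy(),
                                 "std_error": fit.bse.to_numpy()})
            coef.to_csv(out / f"glm_coefficients_{level}.tsv", sep="\t",
                        index=False, float_format="%.10g")
            drop_log.to_csv(out / f"glm_drop_log_{level}.tsv", sep="\t",
                            index=False, float_format="%.10g")
            elevations = sorted(table["elevation"].unique())
            curves = []
            grid = np.arange(fit.jd_range[0], fit.jd_range[1] + 0.5, 1.0)
            level_peaks = {}
            for group in fit.groups or [None]:
                for e in elevations:
                    pred = ph.predict_curve(fit, group, e, grid)
                    curves.append(pd.DataFrame({
                        "group": group, "elevation": e,
                        "julian_day": grid, "fitted": pred}))
                if len(elevations) >= 2:
                    est = ph.peak_delay(fit, group, elevations)
                    level_peaks[group or "all"] = {
                        "delay_per_300m": est.delay_per_300m,
                        "delay_ci": list(est.delay_ci),
                        "n_elevations_used": est.n_elevations_used,
                        "peaks": est.peaks.to_dict(orient="records"),
                    }
                else:
                    report.warnings.append(
                        f"{level}-level model: fewer than two elevations, "
                        f"no delay estimate")
                    level_peaks[group or "all"] = {
                        "delay_per_300m": None, "delay_ci": [None, None],
                        "n_elevations_used": 0, "peaks": []}
            pd.concat(curves, ignore_index=True).to_csv(
                out / f"glm_curves_{level}.tsv", sep="\t", index=False,
                float_format="%.6g")
            peaks_doc[level] = {
                "family": final_spec.family,
                "terms": [ph.term_name(t) for t in final_spec.terms],
                "dispersion": fit.dispersion,
                "groups": level_peaks,
            }
        _write_json(peaks_doc, out / "peaks.json")
        return peaks_doc

    peaks_doc = _stage("phenology")(_phenology)

    # --- overlap ------------------------------------------------------
    def _overlap():
        combined_doc = {}
        for level in config.levels:
            suite = ov.run_overlap_suite(records, level=level, B=config.B,
                                         seed=config.seed)
            suite.site_table().to_csv(out / f"overlap_sites_{level}.tsv",
                                      sep="\t", index=False,
                                      float_format="%.10g")
            combined_doc[level] = {
                f"{t1}|{t2}": {"N": c.N, "K": c.K, "P": c.P}
                for (t1, t2), c in sorted(suite.combined.items())
            }
            if not suite.site_results:
                report.warnings.append(
                    f"no site passed the {level}-level inclusion filter")
            for site, t1, t2, reason in suite.excluded:
                report.warnings.append(
                    f"overlap {level} {t1}-{t2} skipped at {site}: {reason}")
            report.stage_counts[f"overlap_tests_{level}"] = len(suite.site_results)
        _write_json(combined_doc, out / "overlap_combined.json")
        return combined_doc

    _stage("overlap")(_overlap)

    # --- manifest -----------------------------------------------------
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "report.json":
            report.manifest[f.name] = _sha256(f)
    _write_json(report.to_dict(), out / "report.json")
    return report


def format_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    report = json.loads((run_dir / "report.json").read_text())
    lines = [
        "anthonet run summary",
        "====================",
        f"seed: {report['seed']}",
        f"records: {report['stage_counts'].get('records')} "
        f"({report['stage_counts'].get('visits')} visits, "
        f"{report['stage_counts'].get('sites')} sites)",
        "",
        "Community composition (visits by order)",
    ]
    comp = pd.read_csv(run_dir / "composition.tsv", sep="\t")
    for _, row in comp.iterrows():
        lines.append(f"  {row['order']:<14} {int(row['n_visits']):>6} visits "
                     f"({row['pct_visits']:.1f}%), {int(row['n_species'])} species")

    peaks = json.loads((run_dir / "peaks.json").read_text())
    for level, doc in peaks.items():
        lines += ["", f"Phenology peaks ({level} level, {doc['family']} GLM)"]
        for group, g in doc["groups"].items():
            d = g["delay_per_300m"]
            if d is None or d != d:  # no estimate / no interior peaks
                lines.append(f"  {group:<14} no interior peak")
            else:
                lines.append(
                    f"  {group:<14} delay {d:+.1f} d per +300 m "
                    f"(95% CI {g['delay_ci'][0]:.1f} to {g['delay_ci'][1]:.1f}, "
                    f"{g['n_elevations_used']} elevations)")

    combined = json.loads((run_dir / "overlap_combined.json").read_text())
    for level, pairs in combined.items():
        lines += ["", f"Trophic overlap ({level} level)"]
        table_path = run_dir / f"overlap_sites_{level}.tsv"
        sites = pd.read_csv(table_path, sep="\t") if table_path.exists() else None
        if not pairs:
            lines.append("  no qualifying sites")
            continue
        for pair, c in pairs.items():
            t1, t2 = pair.split("|")
            n_sig = ""
            if sites is not None and len(sites):
                sub = sites[(sites.taxon1 == t1) & (sites.taxon2 == t2)]
                n_sig = f", {int(sub.significant.sum())}/{len(sub)} sites significant"
            lines.append(f"  {t1}-{t2}: combined P = {c['P']:.3g} "
                         f"(N = {c['N']}{n_sig})")
    if report["warnings"]:
        lines += ["", f"warnings: {len(report['warnings'])} (see report.json)"]
    return "\n".join(lines) + "\n"
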