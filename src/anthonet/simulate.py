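"""Seeded synthetic visitation data with known ground truth.

The generator emulates a transect study of flower visitors along an
Alpine elevation gradient: a set of meadow sites spanning roughly
970-2700 m, sampled weekly through the flowering season. Each insect
taxon (order or family) has a Gaussian elevational abundance profile, a
Gaussian flight-period phenology whose peak day shifts later with
altitude, and a taxon-level plant-preference distribution from which
its species draw individual preference vectors. Visit counts per
(site, day, insect species, plant) are Poisson with intensity

    lambda = (V_peak / n_species)
             * exp(-(elev - opt)^2 / (2 w_elev^2))          elevation
             * exp(-(jd - mu(elev))^2 / (2 w_pheno^2))      phenology
             * pref[species, plant]                         preference
             * bloom(plant, jd, elev)                       plant bloom

with mu(elev) = base_peak_day + delay * (elev - ref) / 300 and ref the
lowest site elevation. The bloom factor is a Gaussian window truncated
to exactly 0 beyond three bloom widths, which keeps networks sparse.

A null mode draws every species' preference vector from one shared
distribution, making taxon labels exchangeable — the calibration
scenario for the trophic-overlap test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import ReadResult, VisitRecord, read_visits, write_visits

#: Within-taxon Dirichlet concentration: how tightly species of one
#: taxon cluster around their taxon's mean preference.
SPECIES_CONCENTRATION = 60.0


@dataclass(frozen=True)
class TaxonProfile:
    """Generative parameters of one insect taxon (order + family)."""

    order: str
    family: str
    n_species: int
    elevation_optimum: float  # m, centre of the Gaussian abundance profile
    elevation_width: float  # m, its SD (np.inf = elevation-independent)
    base_peak_day: float  # Julian day of peak activity at the reference elevation
    mean_visits_at_peak: float  # expected visits/taxon/day at optimum+peak
    peak_delay_per_300m: float = 7.0  # days of phenological delay per +300 m
    phenology_width: float = 18.0  # days, SD of the flight period
    preference_concentration: float = 0.5  # Dirichlet conc. of the taxon mean;
    # small = spiky mean = distinct preferences

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not (self.elevation_width > 0 and self.phenology_width > 0):
            raise ValueError("widths must be > 0")
        if not self.preference_concentration > 0:
            raise ValueError("preference_concentration must be > 0")
        if self.mean_visits_at_peak < 0:
            raise ValueError("mean_visits_at_peak must be >= 0")


@dataclass(frozen=True)
class PlantProfile:
    """Bloom window of one plant species."""

    plant_species: str
    bloom_peak_day: float  # Julian day at the reference elevation
    bloom_width: float  # days, SD of the bloom window
    bloom_delay_per_300m: float = 7.0

    def __post_init__(self) -> None:
        if not self.bloom_width > 0:
            raise ValueError("bloom_width must be > 0")


@dataclass
class SimulationConfig:
    """Full description of one synthetic sampling campaign."""

    sites: list[tuple[str, float]]  # (site_id, elevation m)
    sampling_days: dict[str, list[int]]  # site_id -> Julian days sampled
    taxa: list[TaxonProfile]
    plants: list[PlantProfile]
    seed: int = 0
    reference_elevation: float | None = None  # default: lowest site

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("need at least one site")
        ids = [s for s, _ in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        for sid, elev in self.sites:
            if elev <= 0:
                raise ValueError(f"elevation must be > 0 for {sid}")
            if sid not in self.sampling_days or not self.sampling_days[sid]:
                raise ValueError(f"no sampling days for site {sid}")
            for d in self.sampling_days[sid]:
                if not 1 <= d <= 366:
                    raise ValueError(f"julian day {d} out of range at {sid}")
        if not self.taxa:
            raise ValueError("need at least one taxon profile")
        if not self.plants:
            raise ValueError("need at least one plant profile")
        names = [p.plant_species for p in self.plants]
        if len(set(names)) != len(names):
            raise ValueError("duplicate plant species")

    @property
    def ref_elevation(self) -> float:
        if self.reference_elevation is not None:
            return self.reference_elevation
        return min(e for _, e in self.sites)


@dataclass
class GroundTruth:
    """Everything the generator knows; substrate of recovery tests."""

    null_mode: bool
    reference_elevation: float
    taxa: list[TaxonProfile]
    plants: list[PlantProfile]
    species_of_taxon: dict[str, list[str]]  # "order/family" -> species names
    preference: dict[str, list[float]]  # species -> preference over plants
    plant_order: list[str]
    true_peak_day: dict[str, dict[str, float]]  # taxon key -> site -> peak JD
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "null_mode": self.null_mode,
            "reference_elevation": self.reference_elevation,
            "taxa": [dataclasses.asdict(t) for t in self.taxa],
            "plants": [dataclasses.asdict(p) for p in self.plants],
            "species_of_taxon": self.species_of_taxon,
            "preference": self.preference,
            "plant_order": self.plant_order,
            "true_peak_day": self.true_peak_day,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            null_mode=d["null_mode"],
            reference_elevation=d["reference_elevation"],
            taxa=[TaxonProfile(**t) for t in d["taxa"]],
            plants=[PlantProfile(**p) for p in d["plants"]],
            species_of_taxon=d["species_of_taxon"],
            preference=d["preference"],
            plant_order=d["plant_order"],
            true_peak_day=d["true_peak_day"],
            seed=d["seed"],
        )


def _taxon_key(t: TaxonProfile) -> str:
    return f"{t.order}/{t.family}" if t.family else t.order


def _gauss(x: np.ndarray | float, mu: float, sd: float) -> np.ndarray | float:
    if np.isinf(sd):
        return np.ones_like(np.asarray(x, dtype=float))
    return np.exp(-((np.asarray(x, dtype=float) - mu) ** 2) / (2.0 * sd**2))


def _bloom_matrix(plants: Sequence[PlantProfile], days: np.ndarray,
                  elev: float, ref: float) -> np.ndarray:
    """(n_plants, n_days) bloom factors, truncated beyond 3 widths."""
    out = np.zeros((len(plants), days.size))
    for j, p in enumerate(plants):
        mu = p.bloom_peak_day + p.bloom_delay_per_300m * (elev - ref) / 300.0
        f = _gauss(days, mu, p.bloom_width)
        if np.isfinite(p.bloom_width):
            f = np.where(np.abs(days - mu) > 3.0 * p.bloom_width, 0.0, f)
        out[j] = f
    return out


def _draw_preferences(
    config: SimulationConfig, rng: np.random.Generator, null_mode: bool
) -> tuple[dict[str, list[str]], dict[str, np.ndarray]]:
    """Species names and preference vectors, taxon-structured or shared."""
    n_plants = len(config.plants)
    shared_mean = None
    if null_mode:
        conc = float(np.mean([t.preference_concentration for t in config.taxa]))
        shared_mean = rng.dirichlet(np.full(n_plants, conc))
    species_of_taxon: dict[str, list[str]] = {}
    preference: dict[str, np.ndarray] = {}
    for t in config.taxa:
        key = _taxon_key(t)
        if null_mode:
            mean = shared_mean
        else:
            mean = rng.dirichlet(np.full(n_plants, t.preference_concentration))
        names = [f"{(t.family or t.order)}_sp{i + 1:03d}" for i in range(t.n_species)]
        species_of_taxon[key] = names
        alpha = SPECIES_CONCENTRATION * mean + 1e-6
        for name in names:
            preference[name] = rng.dirichlet(alpha)
    return species_of_taxon, preference


def simulate_dataset(
    config: SimulationConfig, null_mode: bool = False
) -> tuple[list[VisitRecord], GroundTruth]:
    """Draw one seeded visitation dataset and its ground truth.

    Counts are Poisson with the intensity documented in the module
    docstring; a fixed seed reproduces the records bit-exactly.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.ref_elevation
    species_of_taxon, preference = _draw_preferences(config, rng, null_mode)
    plant_names = [p.plant_species for p in config.plants]

    true_peak: dict[str, dict[str, float]] = {}
    for t in config.taxa:
        key = _taxon_key(t)
        true_peak[key] = {
            sid: t.base_peak_day + t.peak_delay_per_300m * (elev - ref) / 300.0
            for sid, elev in config.sites
        }

    records: list[VisitRecord] = []
    for sid, elev in config.sites:
        days = np.asarray(sorted(config.sampling_days[sid]), dtype=float)
        bloom = _bloom_matrix(config.plants, days, elev, ref)  # (P, D)
        for t in config.taxa:
            key = _taxon_key(t)
            elev_f = float(_gauss(elev, t.elevation_optimum, t.elevation_width))
            mu = true_peak[key][sid]
            pheno = np.asarray(_gauss(days, mu, t.phenology_width))  # (D,)
            base = (t.mean_visits_at_peak / t.n_species) * elev_f
            if base == 0.0:
                continue
            prefs = np.stack([preference[s] for s in species_of_taxon[key]])  # (S, P)
            # intensity (S, P, D)
            lam = base * prefs[:, :, None] * bloom[None, :, :] * pheno[None, None, :]
            counts = rng.poisson(lam)
            for si, pi, di in zip(*np.nonzero(counts)):
                records.append(VisitRecord(
                    site_id=sid,
                    elevation=float(elev),
                    julian_day=int(days[di]),
                    order=t.order,
                    family=t.family,
                    species=species_of_taxon[key][si],
                    plant_species=plant_names[pi],
                    count=int(counts[si, pi, di]),
                ))

    truth = GroundTruth(
        null_mode=null_mode,
        reference_elevation=ref,
        taxa=list(config.taxa),
        plants=list(config.plants),
        species_of_taxon=species_of_taxon,
        preference={k: v.tolist() for k, v in preference.items()},
        plant_order=plant_names,
        true_peak_day=true_peak,
        seed=config.seed,
    )
    return records, truth


def simulate_null_mode(config: SimulationConfig) -> tuple[list[VisitRecord], GroundTruth]:
    """Same generative process with taxon-exchangeable plant preferences."""
    return simulate_dataset(config, null_mode=True)


def write_fixture(
    records: Sequence[VisitRecord],
    ground_truth: GroundTruth,
    directory: str | Path,
    overwrite: bool = False,
) -> tuple[Path, Path]:
    """Persist a dataset as canonical CSV plus ground-truth JSON.

    An existing fixture is never clobbered silently: pass
    ``overwrite=True`` or a versioned filename pair is chosen.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    visits, truth = directory / "visits.csv", directory / "ground_truth.json"
    if not overwrite and (visits.exists() or truth.exists()):
        k = 1
        while (directory / f"visits_{k}.csv").exists() or \
                (directory / f"ground_truth_{k}.json").exists():
            k += 1
        visits = directory / f"visits_{k}.csv"
        truth = directory / f"ground_truth_{k}.json"
    write_visits(records, visits)
    truth.write_text(json.dumps(ground_truth.to_dict(), sort_keys=True, indent=1))
    return visits, truth


def load_fixture(visits_path: str | Path,
                 truth_path: str | Path) -> tuple[ReadResult, GroundTruth]:
    """Inverse of write_fixture."""
    result = read_visits(visits_path)
    truth = GroundTruth.from_dict(json.loads(Path(truth_path).read_text()))
    return result, truth


# ---------------------------------------------------------------------------
# Scenario configurations
# ---------------------------------------------------------------------------

def alpine_campaign_config(seed: int = 0, visit_scale: float = 1.0) -> SimulationConfig:
    """Default scenario: 13 Alpine meadow sites, 972-2659 m.

    Thirteen sites evenly interpolated over the gradient, sampled weekly
    from late May (JD 140) to late July (JD 208). Twelve focal-family
    profiles across the four anthophilous orders reproduce the study
    system's qualitative structure: syrphids peaking ~1500 m, empidids
    ~1800 m, muscids/anthomyiids ~2300 m, bees and most beetles fading
    above ~1400 m, sawflies flat with elevation, butterflies sparse;
    phenology peaks delayed ~7 d per +300 m (10 d for leaf beetles,
    ~1 d for long-horned beetles). Abundance scales are set so the
    expected campaign yields ≈5,500 visits split ≈49/28/18/5% among
    Diptera, Hymenoptera, Coleoptera and Lepidoptera.
    """
    elevations = np.round(np.linspace(972, 2659, 13)).astype(int)
    sites = [(f"S{i + 1:02d}", float(e)) for i, e in enumerate(elevations)]
    days = list(range(140, 209, 7))
    sampling_days = {sid: list(days) for sid, _ in sites}

    s = visit_scale
    # spiky preference means: each family's species concentrate on a
    # handful of the 120 plants, giving realistic diet breadths and
    # a realistic share of order-exclusive plants
    c = dict(preference_concentration=0.08)
    taxa = [
        # Diptera — the dominant order, peaking higher than the rest
        TaxonProfile("Diptera", "Syrphidae", 26, 1500, 450, 160, 51 * s, **c),
        TaxonProfile("Diptera", "Empididae", 16, 1800, 400, 178, 37 * s, **c),
        TaxonProfile("Diptera", "Muscidae", 12, 2300, 400, 170, 34 * s, **c),
        TaxonProfile("Diptera", "Anthomyiidae", 9, 2300, 420, 160, 29 * s, **c),
        # Hymenoptera — bees fade above ~1400 m, sawflies flat
        TaxonProfile("Hymenoptera", "Apidae", 10, 1250, 450, 162, 28 * s, **c),
        TaxonProfile("Hymenoptera", "Halictidae", 13, 1300, 450, 162, 21 * s,
                     **c),
        TaxonProfile("Hymenoptera", "Andrenidae", 7, 1200, 400, 158, 12 * s,
                     **c),
        TaxonProfile("Hymenoptera", "Tenthredinidae", 7, 1800, 900, 165,
                     12 * s, **c),
        # Coleoptera — low-elevation, with distinct family phenologies
        TaxonProfile("Coleoptera", "Chrysomelidae", 10, 1300, 350, 155, 25 * s,
                     peak_delay_per_300m=10.0, **c),
        TaxonProfile("Coleoptera", "Cerambycidae", 9, 1400, 300, 182, 22 * s,
                     peak_delay_per_300m=1.0, **c),
        TaxonProfile("Coleoptera", "Cetoniidae", 6, 1250, 350, 172, 16 * s,
                     **c),
        # Lepidoptera — too scarce per site for the overlap analysis
        TaxonProfile("Lepidoptera", "Nymphalidae", 6, 1300, 500, 185, 17 * s,
                     **c),
    ]
    plants = [
        PlantProfile(f"Plant_{j + 1:03d}",
                     bloom_peak_day=float(142 + (j * 67) % 63),
                     bloom_width=float(12 + (j * 5) % 9))
        for j in range(120)
    ]
    return SimulationConfig(sites=sites, sampling_days=sampling_days,
                            taxa=taxa, plants=plants, seed=seed)


def two_taxa_config(
    seed: int = 0,
    n_species: int = 6,
    n_plants: int = 12,
    mean_visits_at_peak: float = 80.0,
    preference_concentration: float = 0.5,
    n_sites: int = 1,
) -> SimulationConfig:
    """Small two-taxon scenario for overlap-test calibration and power.

    One (or a few) mid-elevation site(s), two orders with identical
    elevation/phenology profiles so any between-taxon difference comes
    from plant preferences alone.
    """
    elevs = np.linspace(1400, 2200, n_sites)
    sites = [(f"S{i + 1:02d}", float(e)) for i, e in enumerate(elevs)]
    days = list(range(150, 201, 5))
    taxa = [
        TaxonProfile("Diptera", "Muscidae", n_species, 1800, np.inf, 172,
                     mean_visits_at_peak, phenology_width=np.inf,
                     preference_concentration=preference_concentration),
        TaxonProfile("Hymenoptera", "Apidae", n_species, 1800, np.inf, 172,
                     mean_visits_at_peak, phenology_width=np.inf,
                     preference_concentration=preference_concentration),
    ]
    plants = [PlantProfile(f"Plant_{j + 1:02d}", 172.0, np.inf)
              for j in range(n_plants)]
    return SimulationConfig(
        sites=sites,
        sampling_days={sid: list(days) for sid, _ in sites},
        taxa=taxa, plants=plants, seed=seed)
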