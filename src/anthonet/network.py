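"""Site-level bipartite visitation networks and descriptive summaries.

A :class:`VisitationNetwork` is the count matrix insect species x plant
species for one site, with each insect species labelled by order and
family. It is the substrate of the trophic-overlap randomization test
and of the exclusivity summary (plants visited by a single focal taxon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .records import UNIDENTIFIED, VisitRecord

TaxonLevel = Literal["order", "family"]

#: Minimum (visits, species-level species) both taxa need at a site for
#: the overlap test, by taxonomic level.
INCLUSION_THRESHOLDS: dict[str, tuple[int, int]] = {
    "order": (50, 10),
    "family": (20, 5),
}


@dataclass
class VisitationNetwork:
    """Bipartite visit-count matrix for one site.

    Attributes
    ----------
    counts
        Integer DataFrame indexed by insect species (rows) and plant
        species (columns). Only species-level visitors appear; visits by
        unresolved specimens are tallied in ``unresolved_visits``.
    taxon_of
        Maps each insect species to its (order, family) labels.
    """

    site_id: str
    elevation: float
    counts: pd.DataFrame
    taxon_of: dict[str, tuple[str, str]]
    unresolved_visits: int = 0
    unresolved_by_taxon: dict[str, int] = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        """Visit count per insect species (matrix row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_visits(self) -> int:
        return int(self.counts.to_numpy().sum())

    def species_of(self, taxon: str, level: TaxonLevel = "order") -> list[str]:
        """Insect species carrying the given order/family label."""
        idx = 0 if level == "order" else 1
        return [s for s in self.counts.index if self.taxon_of[s][idx] == taxon]

    def taxon_stats(self, taxon: str, level: TaxonLevel = "order") -> tuple[int, int]:
        """(n_visits, n_species) of a taxon at this site."""
        species = self.species_of(taxon, level)
        if not species:
            return 0, 0
        return int(self.counts.loc[species].to_numpy().sum()), len(species)

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format weighted bipartite edge list."""
        stacked = self.counts.stack()
        stacked = stacked[stacked > 0]
        rows = [
            {
                "insect_species": insect,
                "plant_species": plant,
                "weight": int(w),
                "order": self.taxon_of[insect][0],
                "family": self.taxon_of[insect][1],
                "site_id": self.site_id,
            }
            for (insect, plant), w in stacked.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["insect_species", "plant_species", "weight", "order",
                     "family", "site_id"],
        )


@dataclass
class ExclusivitySummary:
    """Plants visited by exactly one of the focal taxa, per taxon."""

    level: TaxonLevel
    total_plants: int  # plants visited by >= 1 focal taxon
    exclusive_counts: dict[str, int]
    exclusive_fractions: dict[str, float]
    shared_plants: int

    def __post_init__(self) -> None:
        assert sum(self.exclusive_counts.values()) + self.shared_plants == self.total_plants


def build_network(
    records: Sequence[VisitRecord],
    site_id: str,
    taxon_level: TaxonLevel = "order",
) -> VisitationNetwork:
    """Aggregate one site's records into a bipartite count matrix.

    Species without the resolution the level requires (the UNIDENTIFIED
    sentinel, or an empty family at family level) are excluded from the
    matrix and reported in a side tally, so the matrix only ever feeds
    species-based statistics.
    """
    site_records = [r for r in records if r.site_id == site_id]
    if not site_records:
        available = sorted({r.site_id for r in records})
        raise ValueError(f"no records for site {site_id!r}; available sites: {available}")
    elevation = site_records[0].elevation

    resolved: list[VisitRecord] = []
    unresolved_visits = 0
    unresolved_by_taxon: dict[str, int] = {}
    for r in site_records:
        unresolved = not r.species_level or (taxon_level == "family" and not r.family)
        if unresolved:
            unresolved_visits += r.count
            key = r.order if taxon_level == "order" else (r.family or r.order)
            unresolved_by_taxon[key] = unresolved_by_taxon.get(key, 0) + r.count
        else:
            resolved.append(r)

    taxon_of: dict[str, tuple[str, str]] = {}
    for r in resolved:
        label = (r.order, r.family)
        if taxon_of.setdefault(r.species, label) != label:
            raise ValueError(
                f"species {r.species!r} carries conflicting taxon labels "
                f"{taxon_of[r.species]} and {label} at site {site_id!r}"
            )

    if resolved:
        frame = pd.DataFrame(
            [(r.species, r.plant_species, r.count) for r in resolved],
            columns=["species", "plant", "count"],
        )
        counts = (
            frame.pivot_table(index="species", columns="plant", values="count",
                              aggfunc="sum", fill_value=0)
            .astype(int)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        counts.index.name = None
        counts.columns.name = None
    else:
        counts = pd.DataFrame(dtype=int)
    return VisitationNetwork(
        site_id=site_id,
        elevation=elevation,
        counts=counts,
        taxon_of=taxon_of,
        unresolved_visits=unresolved_visits,
        unresolved_by_taxon=unresolved_by_taxon,
    )


def composition_summary(records: Iterable[VisitRecord]) -> pd.DataFrame:
    """Visit counts, percentage share and species richness per order.

    Richness counts distinct species-level names only; visits by
    unresolved specimens still contribute to abundance, mirroring how
    community composition is usually reported.
    """
    records = list(records)
    if not records:
        return pd.DataFrame(columns=["order", "n_visits", "pct_visits", "n_species"])
    frame = pd.DataFrame(
        [(r.order, r.count, r.species if r.species_level else None) for r in records],
        columns=["order", "count", "species"],
    )
    visits = frame.groupby("order")["count"].sum()
    richness = frame.dropna(subset=["species"]).groupby("order")["species"].nunique()
    out = pd.DataFrame({
        "order": visits.index,
        "n_visits": visits.to_numpy(),
        "pct_visits": 100.0 * visits.to_numpy() / visits.sum(),
        "n_species": richness.reindex(visits.index).fillna(0).astype(int).to_numpy(),
    }).sort_values("n_visits", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def exclusivity_summary(
    network: VisitationNetwork,
    taxa: Sequence[str],
    level: TaxonLevel = "order",
) -> ExclusivitySummary:
    """Count plants visited exclusively by each focal taxon.

    The universe is the plants visited by at least one of the listed
    taxa, and exclusivity is judged within that universe: a plant is
    exclusive to taxon T when every visit it receives from the focal
    taxa comes from species labelled T.
    """
    species_by_taxon = {}
    for taxon in taxa:
        species = network.species_of(taxon, level)
        if not species:
            raise ValueError(f"taxon {taxon!r} absent from site {network.site_id!r}")
        species_by_taxon[taxon] = species

    visited_by: dict[str, set[str]] = {}  # plant -> set of visiting focal taxa
    for taxon, species in species_by_taxon.items():
        block = network.counts.loc[species]
        for plant in block.columns[(block.sum(axis=0) > 0)]:
            visited_by.setdefault(plant, set()).add(taxon)

    exclusive = {t: 0 for t in taxa}
    shared = 0
    for plant, visitors in visited_by.items():
        if len(visitors) == 1:
            exclusive[next(iter(visitors))] += 1
        else:
            shared += 1
    total = len(visited_by)
    fractions = {t: (exclusive[t] / total if total else 0.0) for t in taxa}
    return ExclusivitySummary(
        level=level,
        total_plants=total,
        exclusive_counts=exclusive,
        exclusive_fractions=fractions,
        shared_plants=shared,
    )


def inclusion_filter(
    network: VisitationNetwork,
    taxon1: str,
    taxon2: str,
    level: TaxonLevel = "order",
    min_visits: int | None = None,
    min_species: int | None = None,
) -> tuple[bool, str]:
    """Decide whether a site qualifies for the overlap test of two taxa.

    Both taxa must reach the sampling-adequacy thresholds within the
    site's network: 50 visits and 10 species at order level, 20 visits
    and 5 species at family level (overridable).
    """
    default_visits, default_species = INCLUSION_THRESHOLDS[level]
    need_visits = default_visits if min_visits is None else min_visits
    need_species = default_species if min_species is None else min_species
    for taxon in (taxon1, taxon2):
        visits, species = network.taxon_stats(taxon, level)
        if visits < need_visits:
            return False, (f"{taxon} has {visits} visits < {need_visits} "
                           f"at site {network.site_id}")
        if species < need_species:
            return False, (f"{taxon} has {species} species < {need_species} "
                           f"at site {network.site_id}")
    return True, "both taxa meet the visit and species thresholds"


def write_edge_lists(networks: Iterable[VisitationNetwork], path: str | Path) -> Path:
    """Concatenate per-site edge lists into one TSV."""
    path = Path(path)
    frames = [n.to_edge_list() for n in networks]
    edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["insect_species", "plant_species", "weight", "order", "family", "site_id"])
    edges.to_csv(path, sep="\t", index=False)
    return path
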