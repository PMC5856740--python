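"""Visitation records: the atomic input of the analysis.

One :class:`VisitRecord` is one observed flower visit (or an aggregated
count of identical visits): where it happened (site, elevation), when
(Julian day), who (insect order/family/species or morphospecies) and on
which plant. Records identified above species level carry the sentinel
species name ``UNIDENTIFIED``: they count toward abundance but never
toward species richness or the trophic-overlap test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Sentinel species name for specimens not resolved to species/morphospecies.
UNIDENTIFIED = "UNIDENTIFIED"

#: Canonical column order for visit CSV/TSV files.
CANONICAL_COLUMNS = (
    "site_id",
    "elevation",
    "julian_day",
    "order",
    "family",
    "species",
    "plant_species",
    "count",
)

#: Default label excluded by the honey-bee toggle.
HONEYBEE = "Apis mellifera"


@dataclass(frozen=True)
class VisitRecord:
    """A single (possibly aggregated) insect-flower visitation event."""

    site_id: str
    elevation: float
    julian_day: int
    order: str
    family: str
    species: str
    plant_species: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if not self.elevation > 0:
            raise ValueError(f"elevation must be > 0, got {self.elevation}")
        if not 1 <= self.julian_day <= 366:
            raise ValueError(f"julian_day must be in [1, 366], got {self.julian_day}")
        if not self.order:
            raise ValueError("order must be non-empty")
        if not self.species:
            raise ValueError("species must be non-empty (use the sentinel)")
        if not self.plant_species:
            raise ValueError("plant_species must be non-empty")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def species_level(self) -> bool:
        """True when the visitor is resolved to species/morphospecies."""
        return self.species != UNIDENTIFIED


@dataclass(frozen=True)
class PlantSurveyRecord:
    """Abundance of one blooming plant species on one site-day survey pass."""

    site_id: str
    julian_day: int
    plant_species: str
    abundance: int

    def __post_init__(self) -> None:
        if not 1 <= self.julian_day <= 366:
            raise ValueError(f"julian_day must be in [1, 366], got {self.julian_day}")
        if self.abundance < 0:
            raise ValueError(f"abundance must be >= 0, got {self.abundance}")


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based data-row index in the source file
    reason: str


@dataclass
class ReadResult:
    """Validated records plus a per-row rejection log."""

    records: list[VisitRecord]
    rejections: list[RejectedRow]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_visits(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read and validate visitation records from a delimited text file.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row.
    delimiter
        Field delimiter; inferred from the extension when omitted.
    column_map
        Optional mapping from canonical column name to the name used in
        the file, e.g. ``{"julian_day": "JD"}``. Unmapped canonical names
        must appear verbatim in the header.

    Returns
    -------
    ReadResult
        Rows violating a record invariant (count < 1, Julian day out of
        [1, 366], non-positive elevation, blank taxonomy) are rejected
        individually with a reason; a missing required column is a hard
        error. ``family`` may be empty; an empty ``species`` cell is
        coerced to the ``UNIDENTIFIED`` sentinel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), dtype=str,
                        keep_default_na=False)
    mapping = dict(column_map or {})
    required = [c for c in CANONICAL_COLUMNS if c != "count"]
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = mapping.get(canonical, canonical)
        if source in frame.columns:
            rename[source] = canonical
        elif canonical in required:
            raise ValueError(
                f"required column {canonical!r} (file column {source!r}) "
                f"missing; header has {list(frame.columns)}"
            )
    frame = frame.rename(columns=rename)
    if "count" not in frame.columns:
        frame["count"] = "1"

    records: list[VisitRecord] = []
    rejections: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            records.append(
                VisitRecord(
                    site_id=str(row["site_id"]).strip(),
                    elevation=float(row["elevation"]),
                    julian_day=int(row["julian_day"]),
                    order=str(row["order"]).strip(),
                    family=str(row["family"]).strip(),
                    species=str(row["species"]).strip() or UNIDENTIFIED,
                    plant_species=str(row["plant_species"]).strip(),
                    count=int(row["count"]) if str(row["count"]).strip() else 1,
                )
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RejectedRow(row_number=i, reason=str(exc)))
    return ReadResult(records=records, rejections=rejections)


def write_visits(records: Iterable[VisitRecord], path: str | Path,
                 delimiter: str | None = None) -> Path:
    """Write records to canonical CSV/TSV; round-trips with read_visits."""
    path = Path(path)
    frame = to_frame(records)
    frame.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)
    return path


def to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    """Records as a DataFrame with canonical columns."""
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def exclude_species(records: Sequence[VisitRecord],
                    labels: Sequence[str] = (HONEYBEE,)) -> list[VisitRecord]:
    """Drop visits by the given species labels (honey-bee toggle).

    The managed honey bee can dominate bee visit counts; excluding it
    mirrors the re-analysis in which wild-bee patterns emerge.
    """
    banned = set(labels)
    return [r for r in records if r.species not in banned]
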