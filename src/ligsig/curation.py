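"""Ligand activity table I/O and curation.

Input tables are delimited text with mandatory columns ``smiles``,
``measure_type`` and ``activity_molar`` (molar concentration), plus an
optional ``receptor_id``.  Curation validates molecules, keeps only the
four supported activity measures (Ki, Kd, IC50, EC50), converts molar
activities to the common bioactivity scale -log10(activity), aggregates
replicate measurements of the same compound and removes compounds whose
replicates disagree by more than a configurable spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .chem import MoleculeError, canonical_smiles

MEASURE_TYPES = ("Ki", "Kd", "IC50", "EC50")

#: Sanity band for transformed bioactivities on drug-like data
#: (10^2 molar down to 10^-15 molar covers anything an assay reports).
BIOACTIVITY_SANITY_BAND = (-2.0, 15.0)


@dataclass(frozen=True)
class LigandRecord:
    """One SMILES with one experimental activity measurement."""

    smiles: str
    measure_type: str
    activity_molar: float
    receptor_id: str | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.measure_type not in MEASURE_TYPES:
            raise ValueError(
                f"measure_type must be one of {MEASURE_TYPES}, got {self.measure_type!r}"
            )
        if not (self.activity_molar > 0):
            raise ValueError(f"activity_molar must be positive, got {self.activity_molar}")


@dataclass(frozen=True)
class CuratedLigand:
    """One compound after replicate aggregation, on the -log10 molar scale."""

    smiles: str  # canonical
    bioactivity: float
    n_measurements: int = 1
    measure_types_used: frozenset = field(default_factory=frozenset)
    receptor_id: str | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.bioactivity):
            raise ValueError("bioactivity must be finite")
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")


@dataclass(frozen=True)
class Rejection:
    """Why an input row was excluded from curation."""

    row: int
    smiles: str
    reason: str

    def __str__(self) -> str:  # rejection-log line
        return f"row {self.row}: {self.reason} [{self.smiles}]"


class CurationError(ValueError):
    """Raised on unusable input tables or empty curated results."""


def transform_activity(activity_molar: float) -> float:
    """Convert a molar activity to the bioactivity scale, -log10(activity).

    A Ki of 1 uM (1e-6 M) maps to 6.0; 1 nM to 9.0.  Higher is more
    potent.  The transform makes Ki, Kd, IC50 and EC50 directly
    comparable on one dimensionless scale.
    """
    if not (activity_molar > 0):
        raise ValueError(f"activity must be a positive molar concentration, got {activity_molar}")
    return -math.log10(activity_molar)


def inverse_transform(bioactivity: float) -> float:
    """Molar activity corresponding to a bioactivity value: 10**(-bioactivity)."""
    return 10.0 ** (-bioactivity)


def read_ligand_table(
    source: str | Path | IO[str],
    delimiter: str = ",",
) -> tuple[list[LigandRecord], list[Rejection]]:
    """Read a ligand activity table, validating each row.

    Rows with unparsable SMILES, non-positive activity or an unknown
    measure type are collected in the rejection log with their row
    number (1-based, excluding the header) rather than silently
    dropped.

    Raises
    ------
    CurationError
        If a mandatory column is missing or the table has no rows.
    """
    df = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=True)
    for col in ("smiles", "measure_type", "activity_molar"):
        if col not in df.columns:
            raise CurationError(f"mandatory column {col!r} missing from input table")
    if df.empty:
        raise CurationError("input table has no data rows")

    has_receptor = "receptor_id" in df.columns
    has_decoy = "is_decoy" in df.columns
    records: list[LigandRecord] = []
    rejections: list[Rejection] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        smiles = str(row.smiles).strip()
        measure = str(row.measure_type).strip()
        if measure not in MEASURE_TYPES:
            rejections.append(Rejection(i, smiles, f"unknown measure_type {measure!r}"))
            continue
        try:
            activity = float(row.activity_molar)
        except (TypeError, ValueError):
            rejections.append(Rejection(i, smiles, f"non-numeric activity {row.activity_molar!r}"))
            continue
        if not (activity > 0) or not math.isfinite(activity):
            rejections.append(Rejection(i, smiles, f"non-positive activity {activity}"))
            continue
        try:
            canonical_smiles(smiles)
        except MoleculeError:
            rejections.append(Rejection(i, smiles, "unparsable SMILES"))
            continue
        receptor = None
        if has_receptor:
            val = getattr(row, "receptor_id")
            if isinstance(val, str) and val.strip():
                receptor = val.strip()
        is_decoy = False
        if has_decoy:
            is_decoy = str(getattr(row, "is_decoy")).strip().lower() in ("1", "true", "yes")
        records.append(
            LigandRecord(
                smiles=smiles,
                measure_type=measure,
                activity_molar=activity,
                receptor_id=receptor,
                is_decoy=is_decoy,
            )
        )
    return records, rejections


def write_ligand_table(records: Iterable[LigandRecord], dest, delimiter: str = ",") -> None:
    """Write records in the same dialect read by :func:`read_ligand_table`."""
    rows = [
        {
            "smiles": r.smiles,
            "measure_type": r.measure_type,
            "activity_molar": r.activity_molar,
            "receptor_id": r.receptor_id if r.receptor_id is not None else "",
            "is_decoy": r.is_decoy,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(dest, sep=delimiter, index=False)


def write_curated_table(ligands: Iterable[CuratedLigand], dest, delimiter: str = ",") -> None:
    rows = [
        {
            "smiles": lig.smiles,
            "bioactivity": lig.bioactivity,
            "n_measurements": lig.n_measurements,
            "measure_types_used": "|".join(sorted(lig.measure_types_used)),
            "receptor_id": lig.receptor_id if lig.receptor_id is not None else "",
            "is_decoy": lig.is_decoy,
        }
        for lig in ligands
    ]
    pd.DataFrame(rows).to_csv(dest, sep=delimiter, index=False)


def read_curated_table(source, delimiter: str = ",") -> list[CuratedLigand]:
    df = pd.read_csv(source, sep=delimiter, dtype={"smiles": str})
    ligands = []
    for row in df.itertuples(index=False):
        types = getattr(row, "measure_types_used", "")
        types = frozenset(str(types).split("|")) if isinstance(types, str) and types else frozenset()
        receptor = getattr(row, "receptor_id", None)
        if not isinstance(receptor, str) or not receptor:
            receptor = None
        ligands.append(
            CuratedLigand(
                smiles=row.smiles,
                bioactivity=float(row.bioactivity),
                n_measurements=int(row.n_measurements),
                measure_types_used=types,
                receptor_id=receptor,
                is_decoy=bool(getattr(row, "is_decoy", False)),
            )
        )
    return ligands


def aggregate_replicates(
    records: Sequence[LigandRecord],
    max_spread: float = 1.0,
    statistic: str = "mean",
) -> tuple[list[CuratedLigand], list[str]]:
    """Collapse replicate measurements of the same compound.

    Records are grouped by canonical SMILES of the largest covalent
    component (plus ``receptor_id`` when present).  Groups whose
    transformed bioactivities span more than ``max_spread`` log units
    (max - min) are judged experimentally inconsistent and removed
    entirely; their canonical SMILES are returned as the second item.
    Surviving groups collapse to one :class:`CuratedLigand` whose
    bioactivity is the arithmetic mean (or median) of the transformed
    values — on the molar scale, the geometric mean.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    groups: dict[tuple[str, str | None], list[LigandRecord]] = {}
    canon: dict[int, str] = {}
    for rec in records:
        smi = canonical_smiles(rec.smiles, largest_fragment=True)
        groups.setdefault((smi, rec.receptor_id), []).append(rec)
        canon[id(rec)] = smi

    curated: list[CuratedLigand] = []
    removed: list[str] = []
    for (smi, receptor), grp in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
        values = [transform_activity(r.activity_molar) for r in grp]
        if max(values) - min(values) > max_spread:
            removed.append(smi)
            continue
        if statistic == "mean":
            bio = sum(values) / len(values)
        else:
            srt = sorted(values)
            mid = len(srt) // 2
            bio = srt[mid] if len(srt) % 2 else (srt[mid - 1] + srt[mid]) / 2
        curated.append(
            CuratedLigand(
                smiles=smi,
                bioactivity=bio,
                n_measurements=len(grp),
                measure_types_used=frozenset(r.measure_type for r in grp),
                receptor_id=receptor,
                is_decoy=all(r.is_decoy for r in grp),
            )
        )
    return curated, removed


def curate_dataset(
    records: Sequence[LigandRecord],
    max_spread: float = 1.0,
    statistic: str = "mean",
    measure_types: Sequence[str] | None = None,
) -> list[CuratedLigand]:
    """Validate, filter, transform and aggregate a set of activity records.

    ``measure_types`` restricts the record pool (used by the
    cross-measure experiment, e.g. Ki+Kd only); by default all four
    supported types are pooled together.  Output is sorted by canonical
    SMILES for determinism.

    Raises
    ------
    CurationError
        If nothing survives curation.
    """
    allowed = set(measure_types) if measure_types is not None else set(MEASURE_TYPES)
    kept = []
    for rec in records:
        if rec.measure_type not in allowed:
            continue
        try:
            canonical_smiles(rec.smiles)
        except MoleculeError:
            continue
        kept.append(rec)
    curated, _removed = aggregate_replicates(kept, max_spread=max_spread, statistic=statistic)
    if not curated:
        raise CurationError(
            "no ligands survived curation; dataset too small or too inconsistent"
        )
    return sorted(curated, key=lambda lig: lig.smiles)
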