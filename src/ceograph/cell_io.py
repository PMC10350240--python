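"""Per-cell table I/O: schema, validation, read/write, and patch filters.

A cell table is a delimited text file with one row per segmented nucleus.
Required columns: ``x``, ``y``, ``cell_type``, ``confidence``,
``orientation`` and the ten nuclear morphology columns listed in
:data:`MORPHOLOGY_FEATURES`.  Column-name dialects of upstream tools can be
accommodated with the ``column_map`` option of :func:`read_cell_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Nuclear morphology columns, in the canonical order used for the node
#: feature matrix (after the leading ``confidence`` column).
MORPHOLOGY_FEATURES: tuple[str, ...] = (
    "area",
    "convex_area",
    "eccentricity",
    "extent",
    "filled_area",
    "major_axis_length",
    "minor_axis_length",
    "perimeter_sq_over_area",
    "perimeter",
    "solidity",
)

#: Node feature columns of a spatial graph: confidence then morphology.
NODE_FEATURES: tuple[str, ...] = ("confidence",) + MORPHOLOGY_FEATURES

REQUIRED_COLUMNS: tuple[str, ...] = ("x", "y", "cell_type", "confidence", "orientation") + MORPHOLOGY_FEATURES


class SchemaError(ValueError):
    """A required column is missing from a cell table."""


class ValidationError(ValueError):
    """A cell table row violates a field constraint."""


@dataclass(frozen=True)
class CellTypeScheme:
    """Ordered cell-type vocabulary with an optional pooling subgroup."""

    names: tuple[str, ...]
    subgroup: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("cell type names must be unique")
        if len(self.names) < 1:
            raise ValueError("scheme needs at least one cell type")
        extra = set(self.subgroup) - set(self.names)
        if extra:
            raise ValueError(f"subgroup types not in scheme: {sorted(extra)}")

    @property
    def n_types(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown cell type {name!r}") from None

    def subgroup_indices(self) -> np.ndarray:
        return np.array(sorted(self.index(n) for n in self.subgroup), dtype=np.int64)


#: Lung cancer microenvironment preset: six cell types, tumor subgroup.
LUNG6 = CellTypeScheme(
    names=("tumor", "stroma", "lymphocyte", "red_blood_cell", "macrophage", "karyorrhexis"),
    subgroup=frozenset({"tumor"}),
)

#: Oral epithelium preset: four cell types, epithelial-strata subgroup.
ORAL4 = CellTypeScheme(
    names=("stratum_corneum", "stratum_basale", "other_strata", "non_epithelium"),
    subgroup=frozenset({"stratum_corneum", "stratum_basale", "other_strata"}),
)

SCHEMES: dict[str, CellTypeScheme] = {"lung6": LUNG6, "oral4": ORAL4}


@dataclass(frozen=True)
class CellRecord:
    """One segmented nucleus: position, type, confidence, orientation, morphology."""

    x: float
    y: float
    cell_type: str
    confidence: float
    orientation: float  # degrees in [0, 180); axial (ellipse major axis vs x-axis)
    morphology: tuple[float, ...]  # ten values ordered as MORPHOLOGY_FEATURES

    def morphology_dict(self) -> dict[str, float]:
        return dict(zip(MORPHOLOGY_FEATURES, self.morphology))


@dataclass
class CellTable:
    """All nuclei of one image patch plus provenance identifiers."""

    records: list[CellRecord]
    patch_id: str
    slide_id: str
    patient_id: str
    patch_size_px: int = 1024
    mpp: float = 0.25

    def __len__(self) -> int:
        return len(self.records)

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.cell_type] = counts.get(r.cell_type, 0) + 1
        return counts

    def subgroup_count(self, scheme: CellTypeScheme) -> int:
        sub = scheme.subgroup
        return sum(1 for r in self.records if r.cell_type in sub)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"x": r.x, "y": r.y, "cell_type": r.cell_type, "confidence": r.confidence, "orientation": r.orientation}
            row.update(r.morphology_dict())
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def wrap_orientation(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an axial angle in degrees into [0, 180)."""
    return np.mod(theta, 180.0)


def _validate_row(i: int, row: Mapping[str, float], patch_size_px: int | None) -> None:
    def bad(msg: str) -> ValidationError:
        return ValidationError(f"row {i}: {msg}")

    if not (row["x"] >= 0 and row["y"] >= 0):
        raise bad(f"coordinates must be non-negative, got ({row['x']}, {row['y']})")
    if patch_size_px is not None and not (row["x"] < patch_size_px and row["y"] < patch_size_px):
        raise bad(f"coordinates outside patch of size {patch_size_px}")
    if not (0.0 <= row["confidence"] <= 1.0):
        raise bad(f"confidence {row['confidence']} outside [0, 1]")
    if not (0.0 <= row["eccentricity"] <= 1.0):
        raise bad(f"eccentricity {row['eccentricity']} outside [0, 1]")
    if not (0.0 < row["extent"] <= 1.0):
        raise bad(f"extent {row['extent']} outside (0, 1]")
    if not (0.0 < row["solidity"] <= 1.0):
        raise bad(f"solidity {row['solidity']} outside (0, 1]")
    if row["minor_axis_length"] > row["major_axis_length"] * (1 + 1e-9):
        raise bad("minor_axis_length exceeds major_axis_length")
    if row["area"] > row["convex_area"] * (1 + 1e-9):
        raise bad("area exceeds convex_area")
    for name in MORPHOLOGY_FEATURES:
        v = row[name]
        if not np.isfinite(v) or v < 0:
            raise bad(f"{name} must be finite and non-negative, got {v}")


def validate_table(table: CellTable, scheme: CellTypeScheme) -> None:
    """Raise :class:`ValidationError` on the first invalid record."""
    known = set(scheme.names)
    for i, r in enumerate(table.records):
        if r.cell_type not in known:
            raise ValidationError(f"row {i}: cell type {r.cell_type!r} not in scheme {sorted(known)}")
        row = {"x": r.x, "y": r.y, "confidence": r.confidence}
        row.update(r.morphology_dict())
        _validate_row(i, row, table.patch_size_px)


def read_cell_table(
    path: str | Path,
    scheme: CellTypeScheme,
    *,
    patch_id: str | None = None,
    slide_id: str | None = None,
    patient_id: str | None = None,
    patch_size_px: int = 1024,
    mpp: float = 0.25,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CellTable:
    """Read and validate one per-cell table.

    Parameters
    ----------
    path
        Delimited text file with a header row.  The delimiter is sniffed
        from the suffix (``.tsv`` → tab, otherwise comma) unless ``sep``
        is given.
    scheme
        Cell-type vocabulary; rows with types outside it are rejected.
    column_map
        Optional mapping from this file's column names to the canonical
        snake_case names, for upstream tools with different headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    orient = df["orientation"].to_numpy(dtype=float)
    if np.any((orient < 0) | (orient >= 180.0)):
        warnings.warn(f"{path.name}: orientation values outside [0, 180) wrapped modulo 180", stacklevel=2)
        df = df.assign(orientation=wrap_orientation(orient))

    records = []
    for i, row in enumerate(df.to_dict("records")):
        _validate_row(i, row, patch_size_px)
        if row["cell_type"] not in scheme.names:
            raise ValidationError(f"row {i}: cell type {row['cell_type']!r} not in scheme {list(scheme.names)}")
        records.append(
            CellRecord(
                x=float(row["x"]),
                y=float(row["y"]),
                cell_type=str(row["cell_type"]),
                confidence=float(row["confidence"]),
                orientation=float(row["orientation"]),
                morphology=tuple(float(row[name]) for name in MORPHOLOGY_FEATURES),
            )
        )
    return CellTable(
        records=records,
        patch_id=patch_id or path.stem,
        slide_id=slide_id or path.stem,
        patient_id=patient_id or path.stem,
        patch_size_px=patch_size_px,
        mpp=mpp,
    )


def write_cell_table(table: CellTable, path: str | Path, *, sep: str | None = None) -> Path:
    """Write a cell table as delimited text (lossless round-trip partner of read)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def filter_patches(
    tables: Iterable[CellTable],
    scheme: CellTypeScheme,
    min_subgroup_cells: int,
) -> list[CellTable]:
    """Keep tables with at least ``min_subgroup_cells`` subgroup-type cells.

    The inclusion rule is inclusive ("at least"), so a patch exactly at the
    threshold is retained.  Order is preserved; an empty result is allowed.
    """
    if min_subgroup_cells < 0:
        raise ValueError("min_subgroup_cells must be >= 0")
    return [t for t in tables if t.subgroup_count(scheme) >= min_subgroup_cells]
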