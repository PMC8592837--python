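"""Reading, validation, filtering, and writing of the pipeline's tables.

CSV conventions: header row, UTF-8, "." decimal separator, missing values as
empty fields. Coordinates are 0-based pixel centers; no physical-unit
conversion happens at I/O time.

Cell-table flavors:

* ``hne`` — H&E-derived: requires ``is_lymphocyte`` (0/1).
* ``mihc`` — multiplex IHC: requires at least one marker-intensity column;
  every column not in the core schema is treated as a marker intensity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

REGION_VALUES = ("IT", "PT", "CTRL")

CELL_CORE_COLUMNS = ("cell_id", "patient_id", "core_id", "region", "x_px", "y_px")
CELL_OPTIONAL_COLUMNS = ("is_lymphocyte", "panel_id")

CLINICAL_REQUIRED = ("patient_id", "os_time", "os_event")
CLINICAL_OPTIONAL = (
    "pfs_time",
    "pfs_event",
    "tumor_stage",
    "fuhrman_grade",
    "n_metastatic_organs",
    "mskcc_class",
    "age_years",
    "tumor_size",
    "necrosis",
)


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Columns of a cell table holding marker intensities."""
    known = set(CELL_CORE_COLUMNS) | set(CELL_OPTIONAL_COLUMNS)
    return [c for c in cells.columns if c not in known]


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def validate_cell_table(cells: pd.DataFrame, flavor: str = "hne") -> pd.DataFrame:
    """Validate a cell table in place and return it."""
    if flavor not in ("hne", "mihc"):
        raise ValueError(f"unknown cell-table flavor {flavor!r}")
    _require_columns(cells, CELL_CORE_COLUMNS, "cell table")
    if flavor == "hne":
        _require_columns(cells, ("is_lymphocyte",), "cell table (hne)")
    else:
        if not marker_columns(cells):
            raise SchemaError("cell table (mihc): no marker intensity columns found")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"cell table: duplicated cell_id {dup!r}")
    bad_region = ~cells["region"].isin(REGION_VALUES)
    if bad_region.any():
        raise ValidationError(
            f"cell table: region values outside {REGION_VALUES}: "
            f"{sorted(cells.loc[bad_region, 'region'].unique())}"
        )
    coords = cells[["x_px", "y_px"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        idx = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise ValidationError(f"cell table: non-finite coordinate at row {idx}")
    if "is_lymphocyte" in cells.columns:
        vals = cells["is_lymphocyte"].dropna().unique()
        if not set(np.asarray(vals).astype(float)) <= {0.0, 1.0}:
            raise ValidationError("cell table: is_lymphocyte must be 0/1")
    for col in marker_columns(cells):
        arr = cells[col].to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError(f"cell table: negative intensity in marker {col!r}")
    return cells


def read_cell_table(path: str | Path, flavor: str = "hne") -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_cell_table(df, flavor=flavor)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False, na_rep="")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_clinical_table(df)


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CLINICAL_REQUIRED, "clinical table")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"clinical table: duplicated patient_id {dup!r}")
    if (df["os_time"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("clinical table: os_time must be nonnegative")
    events = df["os_event"].dropna().unique()
    if not set(np.asarray(events).astype(float)) <= {0.0, 1.0}:
        raise ValidationError("clinical table: os_event must be 0/1")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_mutation_table(df)


def validate_mutation_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ("patient_id",), "mutation table")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"mutation table: duplicated patient_id {dup!r}")
    genes = [c for c in df.columns if c != "patient_id"]
    for gene in genes:
        vals = df[gene].dropna().unique()
        if not set(np.asarray(vals).astype(float)) <= {0.0, 1.0}:
            raise ValidationError(
                f"mutation table: gene {gene!r} has values outside {{0, 1, NA}}"
            )
    return df


def write_mutation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def filter_low_cellularity(
    cells: pd.DataFrame,
    min_cells: int = 1500,
    per_region: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Drop tissue cores with fewer than ``min_cells`` cells.

    The threshold is applied per core, counting cells across all of its
    regions; with ``per_region=True`` each core x region is filtered
    separately and the dropped list holds ``(core_id, region)`` pairs.
    Idempotent; an empty input passes through unchanged.
    """
    if cells.empty:
        return cells, []
    if per_region:
        sizes = cells.groupby(["core_id", "region"], sort=False).size()
        dropped = [key for key, n in sizes.items() if n < min_cells]
        if not dropped:
            return cells, []
        keys = pd.MultiIndex.from_frame(cells[["core_id", "region"]])
        keep = ~keys.isin(dropped)
        return cells.loc[keep].copy(), dropped
    sizes = cells.groupby("core_id", sort=False).size()
    dropped = [core for core, n in sizes.items() if n < min_cells]
    if not dropped:
        return cells, []
    return cells.loc[~cells["core_id"].isin(dropped)].copy(), dropped


def write_provenance(path: str | Path, record: dict) -> None:
    """Write a provenance JSON sidecar (filter decisions, seeds, versions)."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
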