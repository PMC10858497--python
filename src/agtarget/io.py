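"""Table dialects and schema-checked CSV reading.

All interchange happens through plain CSV files with documented headers.
Units: acres for land and practice areas, degrees Celsius for
temperatures, millimetres for precipitation, dollars for obligations,
metric tons CO2e per acre per year for sequestration rates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TABLE_SCHEMAS", "read_input_table"]

NA_MARKERS = ["", "NA", "N/A", "NaN", "nan", "(D)", "."]

# kind -> (required columns, numeric columns, allow extra columns)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...], bool]] = {
    "counties": (("county_id", "region_code", "land_area_acres"), ("land_area_acres",), False),
    "census": (
        (
            "county_id",
            "wave_year",
            "cropland_acres",
            "acres_cover_crop",
            "acres_no_till",
            "acres_conservation_till",
        ),
        (
            "wave_year",
            "cropland_acres",
            "acres_cover_crop",
            "acres_no_till",
            "acres_conservation_till",
        ),
        False,
    ),
    "weather": (
        ("county_id", "date", "tmax_c", "tmin_c", "prcp_mm"),
        ("tmax_c", "tmin_c", "prcp_mm"),
        False,
    ),
    "soils": (("county_id",), (), True),  # soil_* columns checked numerically below
    "obligations": (
        ("county_id", "year", "measure", "dollars"),
        ("year", "dollars"),
        False,
    ),
    "sequestration": (
        ("county_id", "cps", "scenario", "joint", "tons_co2e_per_acre_yr"),
        ("tons_co2e_per_acre_yr",),
        False,
    ),
    "geometry_stub": (("county_id",), (), True),
}


def _report_bad_cells(raw: pd.DataFrame, col: str, path: Path) -> None:
    as_num = pd.to_numeric(raw[col], errors="coerce")
    bad = raw[col].notna() & ~raw[col].isin(NA_MARKERS) & as_num.isna()
    if bad.any():
        rows = [int(i) + 2 for i in raw.index[bad][:5]]  # +2: header + 1-basing
        raise ValueError(
            f"{path}: column {col!r} has unparseable numeric cells at file rows {rows}"
        )


def read_input_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one input table; returns a typed DataFrame.

    Checks the header against the documented schema, normalises common
    missing-value markers to NaN, verifies numeric columns cell-by-cell
    (errors cite file row numbers), and logs the shape read.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    required, numeric, allow_extra = TABLE_SCHEMAS[kind]
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, na_values=NA_MARKERS, keep_default_na=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty table (no header)") from None
    if len(raw) == 0:
        raise ValueError(f"{path}: table has a header but no rows")

    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: header mismatch; missing columns {missing_cols}")
    extra = [c for c in raw.columns if c not in required]
    if extra and not allow_extra:
        raise ValueError(f"{path}: unexpected columns {extra}")

    df = raw.copy()
    numeric_cols = list(numeric)
    if kind == "soils":
        numeric_cols += [c for c in df.columns if c.startswith("soil_")]
    for col in numeric_cols:
        _report_bad_cells(raw, col, path)
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if kind == "census":
        df["wave_year"] = df["wave_year"].astype(int)
    if kind == "obligations":
        df["year"] = df["year"].astype(int)
    if kind == "weather":
        df["date"] = pd.to_datetime(df["date"])
    if kind == "sequestration":
        df["joint"] = df["joint"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
        if df["joint"].isna().any():
            raise ValueError(f"{path}: column 'joint' must be boolean")
        df["joint"] = df["joint"].astype(bool)
    logger.info("read %s table %s: %d rows, %d columns", kind, path.name, *df.shape)
    return df


def write_csv(df: pd.DataFrame, path: str | Path, **kwargs) -> Path:
    """Deterministic CSV write used by every pipeline stage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **kwargs)
    return path
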