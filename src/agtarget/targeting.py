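"""Bivariate cost-efficiency classification of counties.

Combines a county's predicted adoption-rate interval with its
sequestration tercile into one of nine classes.  The corner semantics come
from the conceptual model's quadrant reading: slow (negative) adoption with
low sequestration is *inefficient*; fast adoption with low sequestration
yields *cheap but low-quality* credits; slow adoption with high
sequestration buys *expensive but additional* tons; fast adoption with
high sequestration is *cost-effective*.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "mean_sequestration",
    "tercile_assign",
    "rate_intervals",
    "bivariate_classify",
    "export_classification",
    "PRACTICE_CPS",
    "CORNER_LABELS",
]

# Which conservation-practice-standard scenario tags feed each practice:
# tillage reduction averages CPS 345 (reduced till) and 329 (no-till /
# strip-till); cover-cropping averages CPS 340 scenarios.
PRACTICE_CPS = {
    "reduced_till": ("329", "345"),
    "cover_crop": ("340",),
}

RATE_INTERVALS = ("neg", "low_pos", "high_pos")

CORNER_LABELS = {
    ("neg", 1): "inefficient",
    ("high_pos", 1): "cheap-low-quality",
    ("neg", 3): "expensive-additional",
    ("high_pos", 3): "cost-effective",
}


def mean_sequestration(scenario_table: pd.DataFrame, practice: str) -> pd.DataFrame:
    """Per-county mean sequestration over the practice's non-joint scenarios.

    Joint-adoption scenarios (multiple practices at once) are excluded.
    Counties with no eligible scenario get a NaN mean and are flagged.
    Returns columns: county_id, practice, mean_seq, n_scenarios.
    """
    if practice not in PRACTICE_CPS:
        raise ValueError(f"unknown practice {practice!r}")
    cps = PRACTICE_CPS[practice]
    eligible = scenario_table[
        ~scenario_table["joint"] & scenario_table["cps"].astype(str).isin(cps)
    ]
    grouped = eligible.groupby("county_id")["tons_co2e_per_acre_yr"].agg(["mean", "count"])
    out = grouped.rename(columns={"mean": "mean_seq", "count": "n_scenarios"})
    all_counties = scenario_table["county_id"].unique()
    out = out.reindex(all_counties)
    out["n_scenarios"] = out["n_scenarios"].fillna(0).astype(int)
    n_flagged = int(out["mean_seq"].isna().sum())
    if n_flagged:
        logger.warning("%d counties have no eligible %s scenario", n_flagged, practice)
    out.insert(0, "practice", practice)
    return out.reset_index(names="county_id")


def tercile_assign(values: pd.Series | np.ndarray) -> pd.Series:
    """Tercile labels {1,2,3} with breaks at the 1/3 and 2/3 quantiles.

    Quantiles use linear interpolation; intervals are right-closed:
    (-inf, q1], (q1, q2], (q2, inf).  With all values identical every
    defined value lands in tercile 1 (flagged as pathological).  NaNs stay
    unassigned (NA).
    """
    s = pd.Series(values).astype(float)
    defined = s.dropna()
    if len(defined) < 3:
        raise ValueError(f"need >= 3 defined values for terciles, have {len(defined)}")
    q1, q2 = np.quantile(defined.to_numpy(), [1 / 3, 2 / 3])
    if q1 == q2 == defined.max() and defined.nunique() == 1:
        logger.warning("tercile_assign: all values identical; assigning tercile 1")
    out = pd.Series(pd.NA, index=s.index, dtype="Int64")
    out[s <= q1] = 1
    out[(s > q1) & (s <= q2)] = 2
    out[s > q2] = 3
    return out.rename("tercile")


def rate_intervals(predicted: pd.Series | np.ndarray) -> pd.Series:
    """Adoption-rate interval labels: neg / low_pos / high_pos.

    ``neg`` holds rates <= 0 (a rate of exactly zero is grouped with the
    negatives to keep the intervals exhaustive); positive rates split at
    the median of the positive values, right-closed.  NaNs stay NA.
    """
    s = pd.Series(predicted).astype(float)
    out = pd.Series(pd.NA, index=s.index, dtype="string")
    out[s <= 0] = "neg"
    pos = s[s > 0]
    if len(pos):
        med = float(np.median(pos.to_numpy()))
        out[(s > 0) & (s <= med)] = "low_pos"
        out[s > med] = "high_pos"
    return out.rename("rate_interval")


def bivariate_classify(
    rate_interval: pd.Series, seq_tercile: pd.Series
) -> pd.DataFrame:
    """Combine interval and tercile into a 9-class code and label.

    Codes are ``<interval>|T<tercile>``; the four corners carry the
    quadrant-style labels, interior classes use the composite code as
    label.  Rows missing either input get NA class.
    """
    rate_interval, seq_tercile = rate_interval.align(seq_tercile)
    code = pd.Series(pd.NA, index=rate_interval.index, dtype="string")
    label = pd.Series(pd.NA, index=rate_interval.index, dtype="string")
    ok = rate_interval.notna() & seq_tercile.notna()
    for idx in rate_interval.index[ok]:
        interval = str(rate_interval[idx])
        terc = int(seq_tercile[idx])
        c = f"{interval}|T{terc}"
        code[idx] = c
        label[idx] = CORNER_LABELS.get((interval, terc), c)
    return pd.DataFrame({"class_code": code, "class_label": label})


def export_classification(
    rates: pd.Series,
    sequestration: pd.DataFrame,
    practice: str,
    out_path: str | Path | None = None,
    geometry_stub: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One classified row per county for a practice; optional geometry join.

    ``rates`` is indexed by county_id (predicted log acreage ratios);
    ``sequestration`` is a :func:`mean_sequestration` table for the same
    practice.  Counties missing either input are written with missing
    markers.  The exported columns alone are enough to reproduce every
    class code.
    """
    seq = sequestration[sequestration["practice"] == practice].set_index("county_id")
    counties = rates.index.union(seq.index)
    df = pd.DataFrame(index=counties)
    df.index.name = "county_id"
    df["practice"] = practice
    df["predicted_log_ratio"] = rates.reindex(counties)
    df["mean_seq_tCO2e_acre_yr"] = seq["mean_seq"].reindex(counties)
    df["rate_interval"] = rate_intervals(df["predicted_log_ratio"])
    df["seq_tercile"] = tercile_assign(df["mean_seq_tCO2e_acre_yr"])
    classes = bivariate_classify(df["rate_interval"], df["seq_tercile"])
    df = df.join(classes)

    if geometry_stub is not None:
        geo_ids = set(geometry_stub["county_id"])
        missing = [c for c in counties if c not in geo_ids]
        if missing:
            logger.warning("geometry join misses %d counties", len(missing))
        df = df.join(
            geometry_stub.set_index("county_id"), how="left", rsuffix="_geom"
        )

    out = df.reset_index()
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
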