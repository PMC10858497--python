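"""Predictor construction from raw county tables.

Turns census acreage, daily weather, soils and program-obligation tables
into the design matrix used to forecast practice-adoption growth: lagged
adoption share, log lagged acres, degree-bin temperature exposure counts,
seasonal precipitation totals, 20-year climate normals, 5-year weather
deviations, per-acre obligation measures and growing-region indicators.

Missing data is never silently imputed here: counties with missing inputs
are flagged (or dropped with a log entry) and missing obligation measures
are carried as NaN with companion indicator columns added downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonSpec",
    "TEMP_BIN_EDGES",
    "practice_shares",
    "cropland_filter",
    "temperature_exposure",
    "precipitation_totals",
    "annual_exposure",
    "normals_and_deviations",
    "obligation_features",
    "assemble_design_matrix",
]

# bin edges for daily temperature exposure: (-inf,0), [0,10), [10,20),
# [20,30), [30,inf) degrees C; 30.0 itself counts as extreme heat
TEMP_BIN_EDGES = (0.0, 10.0, 20.0, 30.0)
TEMP_BIN_LABELS = ("tlt0", "t0_10", "t10_20", "t20_30", "tge30")
SEASON_LABELS = ("pre", "grow", "post")


@dataclass(frozen=True)
class SeasonSpec:
    """Season boundaries as (month, day) pairs, inclusive of start days.

    Defaults: pre-season Jan 1 - end of Feb, growing season Mar 1 - Aug 31,
    post-season Sep 1 - Dec 31.
    """

    grow_start: tuple[int, int] = (3, 1)
    post_start: tuple[int, int] = (9, 1)

    def assign(self, dates: pd.Series) -> np.ndarray:
        md = dates.dt.month * 100 + dates.dt.day
        grow = self.grow_start[0] * 100 + self.grow_start[1]
        post = self.post_start[0] * 100 + self.post_start[1]
        return np.where(md < grow, "pre", np.where(md < post, "grow", "post"))


def practice_shares(census: pd.DataFrame) -> pd.DataFrame:
    """Per-county, per-wave adoption shares with a shared cropland denominator.

    ``cropland_max`` is the maximum cropland recorded across waves, used as
    the denominator for every wave so shares are comparable over time.
    Reduced-till acres are the sum of no-till and conservation-tillage
    acres.  Counties with non-positive cropland are excluded (logged);
    county-wave cells with missing acres are kept but flagged.
    """
    cropland_max = census.groupby("county_id")["cropland_acres"].max().rename("cropland_max")
    bad = cropland_max[~(cropland_max > 0)]
    if len(bad):
        logger.warning("excluding %d counties with non-positive cropland: %s",
                       len(bad), list(bad.index[:10]))
    cropland_max = cropland_max[cropland_max > 0]

    df = census.merge(cropland_max, on="county_id", how="inner").copy()
    df["acres_reduced_till"] = df["acres_no_till"] + df["acres_conservation_till"]

    long = df.melt(
        id_vars=["county_id", "wave_year", "cropland_max"],
        value_vars=["acres_cover_crop", "acres_reduced_till"],
        var_name="practice",
        value_name="acres",
    )
    long["practice"] = long["practice"].str.removeprefix("acres_")
    long["share"] = long["acres"] / long["cropland_max"]
    long["missing"] = long["acres"].isna()
    return long.sort_values(["county_id", "practice", "wave_year"]).reset_index(drop=True)


def cropland_filter(
    counties: pd.DataFrame,
    cropland_col: str = "cropland_max",
    land_area_col: str = "land_area_acres",
    decile: float = 0.10,
) -> tuple[pd.Index, pd.DataFrame]:
    """Drop counties in the lowest decile of cropland-to-land-area ratio.

    The cutoff is the ``decile`` quantile (linear interpolation) of the
    ratio; counties with ratio <= cutoff are dropped, including boundary
    ties.  With fewer than 10 counties the filter is skipped with a
    warning.  Returns (kept county index, drop log).
    """
    ratio = counties[cropland_col] / counties[land_area_col]
    if len(counties) < 10:
        logger.warning("cropland filter skipped: only %d counties", len(counties))
        return counties.index, pd.DataFrame(columns=["county_id", "ratio", "cutoff"])
    cutoff = float(np.quantile(ratio.to_numpy(), decile))
    dropped = counties.index[ratio <= cutoff]
    if ratio.nunique() == 1:
        logger.warning("cropland filter pathological: all ratios identical; all dropped")
    drop_log = pd.DataFrame(
        {
            "county_id": counties.loc[dropped, "county_id"]
            if "county_id" in counties
            else dropped,
            "ratio": ratio.loc[dropped],
            "cutoff": cutoff,
        }
    )
    kept = counties.index[ratio > cutoff]
    return kept, drop_log


def _daily_index_temperature(
    weather: pd.DataFrame, basis: str = "mean"
) -> pd.Series:
    if basis == "mean":
        return (weather["tmax_c"] + weather["tmin_c"]) / 2.0
    if basis == "tmax":
        return weather["tmax_c"]
    raise ValueError(f"unknown temperature basis {basis!r}")


def temperature_exposure(
    weather: pd.DataFrame,
    season_spec: SeasonSpec = SeasonSpec(),
    basis: str = "mean",
) -> pd.DataFrame:
    """Days per temperature bin per season for each county-year.

    The daily index temperature defaults to (Tmax+Tmin)/2; ``basis='tmax'``
    switches to the daily maximum.  Bins are half-open with the last bin
    [30, inf).  Days with a missing index temperature are tallied in
    ``missing_days``, never imputed.
    """
    df = weather[["county_id", "date"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    temp = _daily_index_temperature(weather, basis)
    df["season"] = season_spec.assign(df["date"])
    df["year"] = df["date"].dt.year
    df["bin"] = pd.cut(
        temp,
        bins=[-np.inf, *TEMP_BIN_EDGES, np.inf],
        right=False,
        labels=TEMP_BIN_LABELS,
    )
    df["missing"] = temp.isna()

    counts = (
        df[~df["missing"]]
        .groupby(["county_id", "year", "season", "bin"], observed=False)
        .size()
        .unstack(["season", "bin"], fill_value=0)
    )
    counts.columns = [f"{s}_{b}" for s, b in counts.columns]
    wanted = [f"{s}_{b}" for s in SEASON_LABELS for b in TEMP_BIN_LABELS]
    counts = counts.reindex(columns=wanted, fill_value=0)
    missing = df.groupby(["county_id", "year"])["missing"].sum().rename("missing_days")
    return counts.join(missing).reset_index()


def precipitation_totals(
    weather: pd.DataFrame, season_spec: SeasonSpec = SeasonSpec()
) -> pd.DataFrame:
    """Seasonal precipitation totals (mm) per county-year."""
    df = weather[["county_id", "date", "prcp_mm"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    df["season"] = season_spec.assign(df["date"])
    df["year"] = df["date"].dt.year
    totals = (
        df.groupby(["county_id", "year", "season"], observed=False)["prcp_mm"]
        .sum(min_count=1)
        .unstack("season")
        .reindex(columns=list(SEASON_LABELS))
    )
    totals.columns = [f"{s}_prcp_mm" for s in totals.columns]
    return totals.reset_index()


def annual_exposure(
    weather: pd.DataFrame,
    season_spec: SeasonSpec = SeasonSpec(),
    basis: str = "mean",
) -> pd.DataFrame:
    """Combined 15 temperature-bin counts + 3 precipitation totals per county-year."""
    temp = temperature_exposure(weather, season_spec, basis)
    prcp = precipitation_totals(weather, season_spec)
    return temp.merge(prcp, on=["county_id", "year"], how="outer")


def normals_and_deviations(
    annual: pd.DataFrame,
    reference_year: int,
    normal_window: int = 20,
    deviation_window: int = 5,
) -> pd.DataFrame:
    """Climate normals and recent-weather deviations per county.

    The normal for each exposure variable is its mean over the
    ``normal_window`` calendar years strictly before ``reference_year``.
    The deviation is the mean of (annual value - normal) over the
    ``deviation_window`` years ending at and including ``reference_year``.
    Counties lacking the full normal window are flagged missing (NaN).
    """
    value_cols = [c for c in annual.columns if c not in ("county_id", "year", "missing_days")]
    normal_years = range(reference_year - normal_window, reference_year)
    dev_years = range(reference_year - deviation_window + 1, reference_year + 1)

    base = annual[annual["year"].isin(normal_years)]
    have = base.groupby("county_id")["year"].nunique()
    complete = have[have == normal_window].index
    incomplete = have[have < normal_window]
    if len(incomplete) or len(have) == 0:
        logger.warning("%d counties lack the full %d-year normal window",
                       len(annual["county_id"].unique()) - len(complete), normal_window)

    normals = base.groupby("county_id")[value_cols].mean()
    normals = normals.loc[normals.index.isin(complete)]
    recent = annual[annual["year"].isin(dev_years)]
    rec_mean = recent.groupby("county_id")[value_cols].mean()
    deviations = (rec_mean - normals).dropna(how="all")

    normals.columns = [f"{c}_normal" for c in normals.columns]
    deviations.columns = [f"{c}_dev" for c in deviations.columns]
    return normals.join(deviations, how="left").reset_index()


def obligation_features(
    obligations: pd.DataFrame,
    cropland_max: pd.Series,
    year_range: tuple[int, int],
) -> pd.DataFrame:
    """Mean annual obligations per cropland acre, one column per measure.

    Each measure's annual dollars are divided by the county's maximum
    cropland acres and averaged over the years in ``year_range``
    (inclusive); missing annual cells are excluded from the mean, with the
    count of contributing years recorded.  A county with no non-missing
    years for a measure gets NaN for that measure.
    """
    y0, y1 = year_range
    if y0 > y1:
        raise ValueError("year_range must be (first, last) with first <= last")
    sub = obligations[(obligations["year"] >= y0) & (obligations["year"] <= y1)].copy()
    sub = sub.merge(cropland_max.rename("cropland_max"), left_on="county_id", right_index=True)
    sub["per_acre"] = sub["dollars"] / sub["cropland_max"]
    agg = sub.groupby(["county_id", "measure"])["per_acre"].agg(["mean", "count"])
    means = agg["mean"].unstack("measure")
    counts = agg["count"].unstack("measure").fillna(0).astype(int)
    means.columns = [f"obl_{c}_per_acre" for c in means.columns]
    counts.columns = [f"obl_{c}_n_years" for c in counts.columns]
    out = means.join(counts)
    # counties present in cropland_max but absent from obligations: all-NaN row
    return out.reindex(cropland_max.index).reset_index(names="county_id")


def assemble_design_matrix(
    shares: pd.DataFrame,
    climate: pd.DataFrame,
    soils: pd.DataFrame,
    obligations: pd.DataFrame,
    regions: pd.DataFrame,
    practice: str,
    wave_pair: tuple[int, int],
    training: bool = True,
    manifest_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join all feature blocks into the forecasting design matrix.

    For wave pair (t-tau, t): ``lagged_share`` = acres_{t-tau}/cropland_max,
    ``log_lagged_acres`` = ln(acres_{t-tau}); the training target is
    ln(acres_t / acres_{t-tau}).  Rows with non-positive lagged acres (or,
    when training, non-positive current acres) are dropped and logged.
    Region codes are one-hot encoded.  Returns (matrix, manifest).
    """
    prev_year, cur_year = wave_pair
    sub = shares[shares["practice"] == practice]
    prev = sub[sub["wave_year"] == prev_year].set_index("county_id")
    cur = sub[sub["wave_year"] == cur_year].set_index("county_id")

    df = pd.DataFrame(index=prev.index)
    df["lagged_share"] = prev["share"]
    df["lagged_acres"] = prev["acres"]
    df["cropland_max"] = prev["cropland_max"]

    dropped: dict[str, list] = {}
    bad_prev = df.index[~(df["lagged_acres"] > 0)]
    if len(bad_prev):
        dropped["nonpositive_lagged_acres"] = list(bad_prev)
        logger.info("dropping %d counties with non-positive lagged acres", len(bad_prev))
    df = df.drop(index=bad_prev)
    df["log_lagged_acres"] = np.log(df["lagged_acres"])

    if training:
        cur_acres = cur["acres"].reindex(df.index)
        bad_cur = df.index[~(cur_acres > 0)]
        if len(bad_cur):
            dropped["nonpositive_current_acres"] = list(bad_cur)
            logger.info("dropping %d counties with non-positive current acres", len(bad_cur))
        df = df.drop(index=bad_cur)
        df["target_log_ratio"] = np.log(cur["acres"].reindex(df.index) / df["lagged_acres"])

    df = df.drop(columns=["lagged_acres", "cropland_max"])

    for name, block in (("climate", climate), ("soils", soils), ("obligations", obligations)):
        b = block.set_index("county_id") if "county_id" in block.columns else block
        missing_keys = df.index.difference(b.index)
        if len(missing_keys) == len(df):
            raise KeyError(f"no overlap between design rows and {name} block")
        df = df.join(b, how="left")

    reg = regions.set_index("county_id") if "county_id" in regions.columns else regions
    onehot = pd.get_dummies(reg["region_code"], prefix="region").astype(float)
    df = df.join(onehot, how="left")

    feature_cols = [c for c in df.columns if c != "target_log_ratio"]
    manifest = {
        "practice": practice,
        "wave_pair": list(wave_pair),
        "n_rows": int(len(df)),
        "feature_columns": feature_cols,
        "target": "target_log_ratio" if training else None,
        "dropped": {k: [str(v) for v in vs] for k, vs in dropped.items()},
        "share_denominator": "raw cropland_max acres",
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return df, manifest
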