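"""Synthetic county panels with the statistical structure the analysis assumes.

The generator produces everything the empirical pipeline consumes — census
practice-acreage tables for two waves, daily weather, soils, program
obligations, and a sequestration-scenario table — plus a *truth* table that
holds the latent quantities (per-practice mean net returns, the held-out
third census wave, true sequestration rates).  The truth table is never read
by pipeline stages; it exists so parameter-recovery tests can compare
predictions against ground truth.

Adoption is generated by the same threshold mechanism the conceptual model
formalises: each county holds ``population`` producers with time-invariant
returns drawn Normal(mu, sigma); a producer adopts in wave ``w`` when their
return plus the common component ``L_w`` is positive.  County adoption
shares therefore match Phi((mu + L_w)/sigma) up to binomial noise, which
ties the generator to the closed form as its oracle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SynthConfig",
    "generate_truth",
    "generate_weather",
    "generate_census_tables",
    "generate_program_tables",
    "write_fixture_bundle",
    "make_forest_fixture",
]

PRACTICES = ("cover_crop", "reduced_till")
REGIONS = ("heartland", "northern_crescent", "prairie_gateway", "eastern_uplands", "fruitful_rim")

# CPS tags mirroring the conservation-practice standards the scenario table
# carries: 329 no-till/strip-till, 345 reduced till, 340 cover crops.
SINGLE_SCENARIOS = {
    "reduced_till": (("329", "no_till_single"), ("345", "reduced_till_single")),
    "cover_crop": (("340", "legume_50pct_n_reduction"), ("340", "nonlegume_25pct_n_reduction")),
}


@dataclass(frozen=True)
class PracticeParams:
    """Latent-return and sequestration structure for one practice."""

    mu_intercept: float
    mu_soil_coefs: tuple[float, ...]
    mu_temp_coef: float
    mu_wet_coef: float
    mu_noise_sd: float
    L_path: tuple[float, float, float]
    # county-level drift added to L per period: dry counties can dis-adopt
    trend_intercept: float
    trend_wet_coef: float
    trend_noise_sd: float
    seq_intercept: float
    seq_soil_coef: float
    seq_temp_coef: float  # applied to -clim_temp: cooler counties sequester more
    seq_wet_coef: float
    seq_noise_sd: float


@dataclass(frozen=True)
class SynthConfig:
    """Generation settings for a county fixture bundle.

    Defaults describe a continental-scale cross-section at reduced size:
    500 counties, census waves five years apart with a held-out third wave,
    cover-crop shares of a few percent and reduced-till shares of roughly a
    third to a half, both drifting upward between waves.
    """

    n_counties: int = 500
    waves: tuple[int, int, int] = (2012, 2017, 2022)
    sigma: float = 1.0  # producer-level net-return sd, dollars
    n_soil: int = 6
    population_range: tuple[int, int] = (200, 1500)
    acres_noise_sd: float = 0.05  # lognormal sd on census acres
    census_missing_frac: float = 0.05
    weather_years: tuple[int, int] = (1997, 2022)  # inclusive
    obligation_years: tuple[int, int] = (2014, 2022)
    obligation_missing_frac: dict[str, float] = field(
        default_factory=lambda: {"all_programs": 0.02, "cover_crop": 0.25, "tillage": 0.25}
    )
    seq_jitter_sd: float = 0.05
    small_county_biased_missingness: bool = False
    practice_params: dict[str, PracticeParams] = field(
        default_factory=lambda: {
            "cover_crop": PracticeParams(
                mu_intercept=-1.6,
                mu_soil_coefs=(0.15, 0.10, 0.0, 0.0, 0.0, 0.0),
                mu_temp_coef=0.10,
                mu_wet_coef=0.20,
                mu_noise_sd=0.25,
                L_path=(0.0, 0.15, 0.30),
                trend_intercept=-0.08,
                trend_wet_coef=0.15,
                trend_noise_sd=0.20,
                seq_intercept=0.30,
                seq_soil_coef=0.04,
                seq_temp_coef=0.05,
                seq_wet_coef=0.08,
                seq_noise_sd=0.05,
            ),
            "reduced_till": PracticeParams(
                mu_intercept=-0.30,
                mu_soil_coefs=(0.20, 0.0, 0.10, 0.0, 0.0, 0.0),
                mu_temp_coef=0.05,
                mu_wet_coef=0.10,
                mu_noise_sd=0.30,
                L_path=(0.0, 0.12, 0.24),
                trend_intercept=-0.06,
                trend_wet_coef=0.10,
                trend_noise_sd=0.18,
                seq_intercept=0.25,
                seq_soil_coef=0.03,
                seq_temp_coef=0.04,
                seq_wet_coef=0.06,
                seq_noise_sd=0.04,
            ),
        }
    )

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        if self.sigma < 0 or self.acres_noise_sd < 0 or self.seq_jitter_sd < 0:
            raise ValueError("variance/scale parameters must be non-negative")
        for name, pp in self.practice_params.items():
            if pp.mu_noise_sd < 0 or pp.seq_noise_sd < 0:
                raise ValueError(f"negative noise scale for practice {name}")
            if len(pp.mu_soil_coefs) != self.n_soil:
                raise ValueError(f"{name}: need {self.n_soil} soil coefficients")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _small_preset() -> SynthConfig:
    return SynthConfig(n_counties=50)


def generate_truth(config: SynthConfig, seed: int) -> pd.DataFrame:
    """Latent county table: covariates, per-practice mu and sequestration truth.

    mu for each practice is a stated linear function of soil and climate
    covariates plus Gaussian noise, so downstream feature/forest stages have
    a recoverable signal.  Deterministic for a fixed ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_counties
    df = pd.DataFrame({"county_id": [f"C{i:04d}" for i in range(n)]})
    df["region_code"] = rng.choice(REGIONS, size=n)
    df["land_area_acres"] = np.round(rng.lognormal(mean=12.8, sigma=0.5, size=n), 0)
    df["population"] = rng.integers(*config.population_range, size=n)

    # latent climate axes reused by weather generator, mu, and sequestration
    clim_temp = rng.normal(0.0, 1.0, size=n)
    clim_wet = rng.normal(0.0, 1.0, size=n)
    df["clim_temp"] = clim_temp
    df["clim_wet"] = clim_wet
    df["temp_mean_c"] = 12.0 + 5.0 * clim_temp
    df["temp_amplitude_c"] = rng.uniform(8.0, 14.0, size=n)
    df["diurnal_range_c"] = rng.uniform(8.0, 12.0, size=n)
    df["precip_wet_prob"] = np.clip(0.25 + 0.08 * clim_wet, 0.05, 0.6)
    df["precip_mean_wet_mm"] = 6.0 * np.exp(0.3 * clim_wet)

    soils = rng.normal(0.0, 1.0, size=(n, config.n_soil))
    for j in range(config.n_soil):
        df[f"soil_{j + 1}"] = soils[:, j]

    # cropland per wave: a stable fraction of land area with small wave drift
    base_frac = rng.uniform(0.10, 0.60, size=n)
    for w, year in enumerate(config.waves):
        drift = rng.normal(0.0, 0.02, size=n)
        frac = np.clip(base_frac + drift, 0.02, 0.95)
        df[f"cropland_acres_{year}"] = np.round(frac * df["land_area_acres"], 0)

    for practice, pp in config.practice_params.items():
        mu = (
            pp.mu_intercept
            + soils @ np.asarray(pp.mu_soil_coefs)
            + pp.mu_temp_coef * clim_temp
            + pp.mu_wet_coef * clim_wet
            + rng.normal(0.0, pp.mu_noise_sd, size=n)
        )
        df[f"mu_{practice}"] = mu
        seq = (
            pp.seq_intercept
            + pp.seq_soil_coef * soils[:, 0]
            + pp.seq_temp_coef * (-clim_temp)
            + pp.seq_wet_coef * clim_wet
            + rng.normal(0.0, pp.seq_noise_sd, size=n)
        )
        df[f"seq_rate_{practice}"] = np.clip(seq, 0.01, None)
        trend = (
            pp.trend_intercept
            + pp.trend_wet_coef * clim_wet
            + rng.normal(0.0, pp.trend_noise_sd, size=n)
        )
        df[f"trend_{practice}"] = trend
        for w, year in enumerate(config.waves):
            df[f"L_{practice}_{year}"] = pp.L_path[w] + trend * w
    return df


def generate_weather(
    truth: pd.DataFrame, years: tuple[int, int], seed: int
) -> pd.DataFrame:
    """Daily Tmax/Tmin/precip per county: seasonal sinusoid + county offset + noise.

    Temperature peaks in midsummer (day-of-year ~200).  The diurnal
    half-range is strictly positive so ``tmax >= tmin`` holds by
    construction.  Precipitation is intermittent: Bernoulli wet days with
    gamma-distributed amounts.
    """
    if years[0] > years[1]:
        raise ValueError("years must be a (first, last) contiguous range")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n_c, n_d = len(truth), len(dates)

    seasonal = -np.cos(2 * np.pi * (doy - 18) / 365.25)  # trough mid-January
    tmean = (
        truth["temp_mean_c"].to_numpy()[:, None]
        + truth["temp_amplitude_c"].to_numpy()[:, None] * seasonal[None, :]
        + rng.normal(0.0, 3.0, size=(n_c, n_d))
    )
    half_range = np.maximum(
        truth["diurnal_range_c"].to_numpy()[:, None] / 2.0
        + rng.normal(0.0, 1.0, size=(n_c, n_d)),
        0.5,
    )
    wet = rng.random(size=(n_c, n_d)) < truth["precip_wet_prob"].to_numpy()[:, None]
    amounts = rng.gamma(
        0.8, truth["precip_mean_wet_mm"].to_numpy()[:, None] / 0.8, size=(n_c, n_d)
    )
    prcp = np.where(wet, amounts, 0.0)

    out = pd.DataFrame(
        {
            "county_id": np.repeat(truth["county_id"].to_numpy(), n_d),
            "date": np.tile(dates.to_numpy(), n_c),
            "tmax_c": np.round((tmean + half_range).ravel(), 3),
            "tmin_c": np.round((tmean - half_range).ravel(), 3),
            "prcp_mm": np.round(prcp.ravel(), 3),
        }
    )
    return out


def _adopter_shares(truth: pd.DataFrame, config: SynthConfig, rng: np.random.Generator):
    """Draw producer returns once per county-practice; count adopters per wave.

    Counties whose per-county L path declines show dis-adoption (producers
    fall below threshold).  Marginally each wave's adopter count is
    Binomial(population, Phi((mu + L_w)/sigma)).
    """
    shares: dict[tuple[str, int], np.ndarray] = {}
    pops = truth["population"].to_numpy()
    for practice in config.practice_params:
        mu = truth[f"mu_{practice}"].to_numpy()
        L_by_wave = [truth[f"L_{practice}_{year}"].to_numpy() for year in config.waves]
        counts = np.zeros((len(truth), len(config.waves)))
        for i, (m, pop) in enumerate(zip(mu, pops)):
            r = rng.normal(m, config.sigma, size=int(pop))
            for w in range(len(config.waves)):
                counts[i, w] = np.count_nonzero(r + L_by_wave[w][i] > 0)
        for w, year in enumerate(config.waves):
            shares[(practice, year)] = counts[:, w] / pops
    return shares


def generate_census_tables(
    truth: pd.DataFrame, config: SynthConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Practice-acreage census for the first two waves, plus held-out truth.

    Returns ``(census, heldout)``.  ``census`` has one row per county per
    published wave with cropland and acre columns for cover crops, no-till
    and conservation tillage (reduced till = no-till + conservation till);
    a configurable fraction of county-wave-practice cells is set missing.
    ``heldout`` carries the third wave's true acres and shares and is stored
    with the truth table only.
    """
    rng = np.random.default_rng(seed)
    shares = _adopter_shares(truth, config, rng)
    n = len(truth)
    published_waves = config.waves[:2]
    heldout_wave = config.waves[2]

    nt_frac = rng.uniform(0.4, 0.8, size=n)  # county split of reduced-till acres

    rows = []
    for year in config.waves:
        cropland = truth[f"cropland_acres_{year}"].to_numpy()
        rec = {
            "county_id": truth["county_id"].to_numpy(),
            "wave_year": year,
            "cropland_acres": cropland,
        }
        for practice in PRACTICES:
            noise = np.exp(rng.normal(0.0, config.acres_noise_sd, size=n))
            acres = shares[(practice, year)] * cropland * noise
            if practice == "reduced_till":
                rec["acres_no_till"] = np.round(acres * nt_frac, 1)
                rec["acres_conservation_till"] = np.round(acres * (1 - nt_frac), 1)
            else:
                rec["acres_cover_crop"] = np.round(acres, 1)
            rec[f"share_{practice}_true"] = shares[(practice, year)]
        rows.append(pd.DataFrame(rec))
    all_waves = pd.concat(rows, ignore_index=True)

    census = all_waves[all_waves["wave_year"].isin(published_waves)].copy()
    census = census.drop(columns=[c for c in census.columns if c.endswith("_true")])
    # MCAR (optionally small-county-biased) missingness on practice cells
    for cols in (["acres_cover_crop"], ["acres_no_till", "acres_conservation_till"]):
        if config.small_county_biased_missingness:
            size_rank = census["cropland_acres"].rank(pct=True).to_numpy()
            p_miss = config.census_missing_frac * 2.0 * (1.0 - size_rank)
        else:
            p_miss = np.full(len(census), config.census_missing_frac)
        mask = rng.random(len(census)) < p_miss
        census.loc[mask, cols] = np.nan

    heldout = all_waves[all_waves["wave_year"] == heldout_wave].copy()
    heldout = heldout.rename(
        columns={
            "acres_cover_crop": "acres_cover_crop_heldout",
            "acres_no_till": "acres_no_till_heldout",
            "acres_conservation_till": "acres_conservation_till_heldout",
        }
    )
    heldout["acres_reduced_till_heldout"] = (
        heldout["acres_no_till_heldout"] + heldout["acres_conservation_till_heldout"]
    )
    return census.reset_index(drop=True), heldout.reset_index(drop=True)


def generate_program_tables(
    truth: pd.DataFrame, config: SynthConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Obligations (long: county x year x measure) and sequestration scenarios.

    Obligation measures mirror the three aggregations used downstream
    (all-programs total, cover-crop practices, tillage practices) with
    heavier missingness on the practice-specific measures, mimicking
    disclosure suppression.  The sequestration table holds two
    single-practice scenarios per practice per county, jittered around the
    county's true rate, plus joint-adoption rows flagged for exclusion.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    y0, y1 = config.obligation_years
    years = list(range(y0, y1 + 1))

    cropland = truth[[c for c in truth.columns if c.startswith("cropland_acres_")]].max(axis=1)
    base_total = cropland.to_numpy() * rng.lognormal(0.0, 0.6, size=n) * 2.0
    share_cc = rng.uniform(0.05, 0.20, size=n)
    share_till = rng.uniform(0.08, 0.25, size=n)

    obl_rows = []
    for year in years:
        wobble = rng.lognormal(0.0, 0.25, size=n)
        total = np.round(base_total * wobble, 2)
        obl_rows.append(
            pd.DataFrame(
                {
                    "county_id": truth["county_id"],
                    "year": year,
                    "measure": "all_programs",
                    "dollars": total,
                }
            )
        )
        obl_rows.append(
            pd.DataFrame(
                {
                    "county_id": truth["county_id"],
                    "year": year,
                    "measure": "cover_crop",
                    "dollars": np.round(total * share_cc, 2),
                }
            )
        )
        obl_rows.append(
            pd.DataFrame(
                {
                    "county_id": truth["county_id"],
                    "year": year,
                    "measure": "tillage",
                    "dollars": np.round(total * share_till, 2),
                }
            )
        )
    obligations = pd.concat(obl_rows, ignore_index=True)
    keep = np.ones(len(obligations), dtype=bool)
    for measure, frac in config.obligation_missing_frac.items():
        idx = (obligations["measure"] == measure).to_numpy()
        keep[idx] &= rng.random(idx.sum()) >= frac
    obligations = obligations[keep].reset_index(drop=True)

    seq_rows = []
    for practice in PRACTICES:
        true_rate = truth[f"seq_rate_{practice}"].to_numpy()
        for cps, scenario in SINGLE_SCENARIOS[practice]:
            vals = np.clip(true_rate + rng.normal(0.0, config.seq_jitter_sd, size=n), 0.0, None)
            seq_rows.append(
                pd.DataFrame(
                    {
                        "county_id": truth["county_id"],
                        "cps": cps,
                        "scenario": scenario,
                        "joint": False,
                        "tons_co2e_per_acre_yr": np.round(vals, 4),
                    }
                )
            )
    joint_rate = (
        truth["seq_rate_cover_crop"].to_numpy() + truth["seq_rate_reduced_till"].to_numpy()
    ) * 0.8
    seq_rows.append(
        pd.DataFrame(
            {
                "county_id": truth["county_id"],
                "cps": "329+340",
                "scenario": "no_till_with_cover_crop",
                "joint": True,
                "tons_co2e_per_acre_yr": np.round(
                    np.clip(joint_rate + rng.normal(0.0, config.seq_jitter_sd, size=n), 0.0, None),
                    4,
                ),
            }
        )
    )
    sequestration = pd.concat(seq_rows, ignore_index=True)
    return obligations, sequestration


def expected_shares(truth: pd.DataFrame, config: SynthConfig, practice: str, year: int):
    """Closed-form adoption shares Phi((mu + L_year)/sigma) for checking."""
    mu = truth[f"mu_{practice}"].to_numpy()
    L = truth[f"L_{practice}_{year}"].to_numpy()
    return norm.cdf((mu + L) / config.sigma)


def write_fixture_bundle(config: SynthConfig, seed: int, out_dir: str | Path) -> dict:
    """Generate every table and write the bundle as CSVs plus a manifest.

    Regenerating with the same (config, seed) produces byte-identical files.
    Returns the manifest dict (paths, seed, config hash, file hashes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # independent deterministic streams per table
    truth = generate_truth(config, seed)
    weather = generate_weather(truth, config.weather_years, seed + 1)
    census, heldout = generate_census_tables(truth, config, seed + 2)
    obligations, sequestration = generate_program_tables(truth, config, seed + 3)

    counties = truth[["county_id", "region_code", "land_area_acres"]]
    soils = truth[["county_id"] + [f"soil_{j + 1}" for j in range(config.n_soil)]]
    geometry = truth[["county_id"]]
    truth_full = truth.merge(
        heldout.drop(columns=["wave_year", "cropland_acres"]), on="county_id"
    )

    tables = {
        "counties": counties,
        "census": census,
        "weather": weather,
        "soils": soils,
        "obligations": obligations,
        "sequestration": sequestration,
        "geometry_stub": geometry,
        "truth": truth_full,
    }
    manifest: dict = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "files": {},
    }
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"path": path.name, "sha256": digest, "rows": len(df)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_forest_fixture(
    n_counties: int = 500,
    n_predictors: int = 20,
    seed: int = 0,
    practice: str = "cover_crop",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Compact design-matrix fixture for forest calibration experiments.

    Builds (X, y, X_future, y_future) from a generated county panel: X
    holds the lagged adoption share, log lagged acres, soil covariates,
    region indicators and pure-noise fillers up to ``n_predictors``
    columns; y is the wave-1 -> wave-2 log acreage ratio.  ``X_future``
    rebuilds the lagged columns from wave 2, and ``y_future`` is the
    held-out wave-2 -> wave-3 log ratio, enabling parameter-recovery
    checks.  No weather aggregation is involved, so replicated fits stay
    cheap.
    """
    config = SynthConfig(n_counties=n_counties, census_missing_frac=0.0)
    truth = generate_truth(config, seed)
    census, heldout = generate_census_tables(truth, config, seed + 2)

    w1, w2, w3 = config.waves
    if practice == "cover_crop":
        acres = census.pivot(index="county_id", columns="wave_year", values="acres_cover_crop")
        acres_h = heldout.set_index("county_id")["acres_cover_crop_heldout"]
    else:
        wide_nt = census.pivot(index="county_id", columns="wave_year", values="acres_no_till")
        wide_ct = census.pivot(
            index="county_id", columns="wave_year", values="acres_conservation_till"
        )
        acres = wide_nt + wide_ct
        acres_h = heldout.set_index("county_id")["acres_reduced_till_heldout"]

    t = truth.set_index("county_id")
    cropland_max = t[[f"cropland_acres_{w}" for w in (w1, w2)]].max(axis=1)

    rng = np.random.default_rng(seed + 9)

    def build_X(lag_wave) -> pd.DataFrame:
        X = pd.DataFrame(index=acres.index)
        X["lagged_share"] = acres[lag_wave] / cropland_max
        X["log_lagged_acres"] = np.log(acres[lag_wave].clip(lower=1e-9))
        # climate covariates, mirroring the normals the full design matrix has
        X["temp_mean"] = t["temp_mean_c"]
        X["wet_prob"] = t["precip_wet_prob"]
        X["wet_intensity"] = t["precip_mean_wet_mm"]
        for j in range(config.n_soil):
            X[f"soil_{j + 1}"] = t[f"soil_{j + 1}"]
        region_dummies = pd.get_dummies(t["region_code"], prefix="region").astype(float)
        return X.join(region_dummies)

    X = build_X(w1)
    X_future = build_X(w2)
    noise = {f"noise_{k}": rng.normal(size=len(X)) for k in range(1, max(0, n_predictors - X.shape[1]) + 1)}
    for name, vals in noise.items():  # same noise columns in both periods
        X[name] = vals
        X_future[name] = vals
    X = X.iloc[:, :n_predictors]
    X_future = X_future.iloc[:, :n_predictors]

    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(acres[w2] / acres[w1])
        y_future = np.log(acres_h / acres[w2])
    ok = y.notna() & y_future.notna() & np.isfinite(y) & np.isfinite(y_future)
    ok &= (acres[w1] > 0) & (acres[w2] > 0) & (acres_h > 0)
    return (
        X.loc[ok],
        y.loc[ok].rename("log_ratio"),
        X_future.loc[ok],
        y_future.loc[ok].rename("log_ratio_future"),
    )
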