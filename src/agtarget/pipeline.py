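"""Configuration and the end-to-end forecasting/classification pipeline.

Stages (each restartable from its predecessors' files):

1. ``stage_features`` — practice shares, cropland decile filter, exposure
   aggregation, normals/deviations, obligation measures; writes the
   training and prediction design matrices per practice.
2. ``stage_train`` — iterative honest-forest training on the wave-1 ->
   wave-2 log acreage ratio; writes the fitted model, out-of-bag
   predictions, calibration-test results and split importances.
3. ``stage_predict`` — forecasts the wave-2 -> wave-3 log ratio from the
   prediction design matrix.
4. ``stage_classify`` — sequestration-scenario averaging, rate intervals,
   terciles and the 9-class bivariate classification table.

All randomness flows from the per-practice forest seeds in the config, so
two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as F
from . import forest as RF
from . import targeting as T
from .io import read_input_table, write_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline",
           "stage_features", "stage_train", "stage_predict", "stage_classify"]

PRACTICE_DEFAULT_FOREST = {
    "reduced_till": RF.TILLAGE_FOREST_CONFIG,
    "cover_crop": RF.COVER_CROP_FOREST_CONFIG,
}

OBLIGATION_MEASURE_BY_PRACTICE = {"cover_crop": "cover_crop", "reduced_till": "tillage"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings; see ``load_config`` for the file format."""

    paths: dict[str, str]
    out_dir: str
    waves: tuple[int, int, int] = (2012, 2017, 2022)
    practices: tuple[str, ...] = ("cover_crop", "reduced_till")
    season: F.SeasonSpec = field(default_factory=F.SeasonSpec)
    temperature_basis: str = "mean"
    normal_window: int = 20
    deviation_window: int = 5
    obligation_train_years: tuple[int, int] = (2014, 2017)
    obligation_predict_years: tuple[int, int] = (2018, 2022)
    cropland_decile: float = 0.10
    forest: dict[str, RF.ForestConfig] = field(default_factory=dict)
    seed: int = 0
    classify: bool = True

    def forest_config(self, practice: str) -> RF.ForestConfig:
        base = self.forest.get(practice, PRACTICE_DEFAULT_FOREST[practice])
        # practice-distinct deterministic seed offsets from the config seed
        offset = 100 * (1 + sorted(self.practices).index(practice))
        return dataclasses.replace(base, seed=base.seed + self.seed + offset)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


_REQUIRED_PATH_KEYS = ("counties", "census", "weather", "soils", "obligations", "sequestration")
_OPTIONAL_PATH_KEYS = ("geometry",)
_FOREST_KEYS = {f.name for f in dataclasses.fields(RF.ForestConfig)}
_TOP_KEYS = {
    "paths", "out_dir", "waves", "practices", "season", "temperature_basis",
    "normal_window", "deviation_window", "obligation_train_years",
    "obligation_predict_years", "cropland_decile", "forest", "seed", "classify",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected.

    Required keys: ``paths`` (counties, census, weather, soils,
    obligations, sequestration; optional geometry) and ``out_dir``.  Forest
    parameters default per practice; season dates and windows default to
    the documented conventions.  Defaults that get filled are logged.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for req in ("paths", "out_dir"):
        if req not in raw:
            raise ValueError(f"config missing required key: {req}")

    paths = dict(raw["paths"])
    unknown_paths = set(paths) - set(_REQUIRED_PATH_KEYS) - set(_OPTIONAL_PATH_KEYS)
    if unknown_paths:
        raise ValueError(f"unknown path keys: {sorted(unknown_paths)}")
    missing = [k for k in _REQUIRED_PATH_KEYS if k not in paths]
    if missing:
        raise ValueError(f"config paths missing: {missing}")
    for key, p in paths.items():
        if not Path(p).exists():
            raise ValueError(f"input path for {key!r} does not exist: {p}")

    kwargs: dict = {"paths": paths, "out_dir": raw["out_dir"]}
    for key in ("temperature_basis", "normal_window", "deviation_window",
                "cropland_decile", "seed", "classify"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("waves", "practices", "obligation_train_years", "obligation_predict_years"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "season" in raw:
        season = raw["season"]
        unknown_season = set(season) - {"grow_start", "post_start"}
        if unknown_season:
            raise ValueError(f"unknown season keys: {sorted(unknown_season)}")
        kwargs["season"] = F.SeasonSpec(
            grow_start=tuple(season.get("grow_start", (3, 1))),
            post_start=tuple(season.get("post_start", (9, 1))),
        )
    if "forest" in raw:
        forest_cfgs = {}
        for practice, params in raw["forest"].items():
            unknown_f = set(params) - _FOREST_KEYS
            if unknown_f:
                raise ValueError(f"unknown forest keys for {practice}: {sorted(unknown_f)}")
            base = dataclasses.asdict(PRACTICE_DEFAULT_FOREST[practice])
            base.update(params)
            forest_cfgs[practice] = RF.ForestConfig(**base)
        kwargs["forest"] = forest_cfgs

    config = PipelineConfig(**kwargs)
    defaults_filled = sorted(_TOP_KEYS - set(raw))
    logger.info("config loaded from %s; defaults filled for: %s", path, defaults_filled)
    return config


# ---------------------------------------------------------------------------
# stages


def _load_inputs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    tables = {k: read_input_table(config.paths[k], k) for k in _REQUIRED_PATH_KEYS}
    if "geometry" in config.paths:
        tables["geometry"] = read_input_table(config.paths["geometry"], "geometry_stub")
    return tables


def stage_features(config: PipelineConfig) -> dict:
    """Build and write the per-practice training/prediction design matrices."""
    tables = _load_inputs(config)
    w1, w2, w3 = config.waves
    log: dict = {"stage": "features", "counts": {}}

    shares = F.practice_shares(tables["census"])
    log["counts"]["counties_in_census"] = int(shares["county_id"].nunique())

    cropmax = shares.groupby("county_id")["cropland_max"].first()
    counties = tables["counties"].merge(
        cropmax.reset_index(), on="county_id", how="inner"
    )
    kept_idx, drop_log = F.cropland_filter(
        counties, "cropland_max", "land_area_acres", config.cropland_decile
    )
    kept_ids = set(counties.loc[kept_idx, "county_id"])
    log["counts"]["dropped_cropland_decile"] = int(len(drop_log))
    log["counts"]["kept_after_decile_filter"] = len(kept_ids)
    shares = shares[shares["county_id"].isin(kept_ids)]

    annual = F.annual_exposure(tables["weather"], config.season, config.temperature_basis)
    climate_train = F.normals_and_deviations(
        annual, w2, config.normal_window, config.deviation_window
    )
    climate_pred = F.normals_and_deviations(
        annual, w3, config.normal_window, config.deviation_window
    )

    obl_train = F.obligation_features(
        tables["obligations"], cropmax, config.obligation_train_years
    )
    obl_pred = F.obligation_features(
        tables["obligations"], cropmax, config.obligation_predict_years
    )
    # the n_years bookkeeping columns are diagnostics, not predictors
    obl_train = obl_train[[c for c in obl_train.columns if not c.endswith("_n_years")]]
    obl_pred = obl_pred[[c for c in obl_pred.columns if not c.endswith("_n_years")]]

    soils = tables["soils"]
    regions = tables["counties"][["county_id", "region_code"]]

    out_paths: dict[str, dict[str, str]] = {}
    for practice in config.practices:
        X_train, manifest_train = F.assemble_design_matrix(
            shares, climate_train, soils, obl_train, regions,
            practice=practice, wave_pair=(w1, w2), training=True,
            manifest_path=config.out / f"design_train_{practice}.manifest.json",
        )
        X_pred, manifest_pred = F.assemble_design_matrix(
            shares, climate_pred, soils, obl_pred, regions,
            practice=practice, wave_pair=(w2, w3), training=False,
            manifest_path=config.out / f"design_predict_{practice}.manifest.json",
        )
        p_train = write_csv(
            X_train.reset_index(), config.out / f"design_train_{practice}.csv"
        )
        p_pred = write_csv(
            X_pred.reset_index(), config.out / f"design_predict_{practice}.csv"
        )
        out_paths[practice] = {"train": str(p_train), "predict": str(p_pred)}
        log["counts"][f"train_rows_{practice}"] = int(len(X_train))
        log["counts"][f"predict_rows_{practice}"] = int(len(X_pred))
        log["counts"][f"dropped_{practice}"] = {
            k: len(v) for k, v in manifest_train["dropped"].items()
        }
    log["design_paths"] = out_paths
    _append_log(config, log)
    return log


def _read_design(config: PipelineConfig, practice: str, which: str) -> pd.DataFrame:
    path = config.out / f"design_{which}_{practice}.csv"
    if not path.exists():
        raise FileNotFoundError(f"{path} not found; run the features stage first")
    return pd.read_csv(path).set_index("county_id")


def stage_train(config: PipelineConfig) -> dict:
    """Iterative honest-forest training, calibration test, importances."""
    log: dict = {"stage": "train", "practices": {}}
    for practice in config.practices:
        X_full = _read_design(config, practice, "train")
        y = X_full.pop("target_log_ratio")
        cfg = config.forest_config(practice)
        selected, model, stage1 = RF.iterative_train(X_full, y, cfg)
        model.save(config.out / f"model_{practice}")
        (config.out / f"model_{practice}" / "selected.json").write_text(
            json.dumps({"selected": selected, "all": list(X_full.columns)}, indent=2)
        )

        oob, n_oob = RF.oob_predict(model, X_full[selected])
        write_csv(
            pd.DataFrame(
                {
                    "county_id": X_full.index,
                    "oob_prediction": oob,
                    "n_oob_trees": n_oob,
                    "target_log_ratio": y.to_numpy(),
                }
            ),
            config.out / f"oob_{practice}.csv",
        )
        cal = RF.calibration_test(oob, y.to_numpy())
        (config.out / f"calibration_{practice}.json").write_text(
            json.dumps(dataclasses.asdict(cal), indent=2, sort_keys=True)
        )
        imp1 = RF.split_importance(stage1)
        imp2 = RF.split_importance(model)
        write_csv(
            pd.concat(
                [imp1.rename("stage1_importance"), imp2.rename("final_importance")], axis=1
            ).reset_index(names="predictor"),
            config.out / f"importance_{practice}.csv",
        )
        log["practices"][practice] = {
            "n_train": int(model.n_train),
            "selected": selected,
            "mean_pred_coef": cal.mean_pred_coef,
            "diff_pred_coef": cal.diff_pred_coef,
        }
    _append_log(config, log)
    return log


def stage_predict(config: PipelineConfig) -> dict:
    """Forecast wave-2 -> wave-3 log acreage ratios per practice."""
    log: dict = {"stage": "predict", "practices": {}}
    for practice in config.practices:
        model = RF.ForestModel.load(config.out / f"model_{practice}")
        selected = json.loads(
            (config.out / f"model_{practice}" / "selected.json").read_text()
        )["selected"]
        X_pred = _read_design(config, practice, "predict")
        preds = RF.predict_forest(model, X_pred[selected])
        write_csv(
            pd.DataFrame(
                {
                    "county_id": X_pred.index,
                    "predicted_log_ratio": preds,
                    "n_oob_trees": np.nan,  # not applicable to non-training rows
                }
            ),
            config.out / f"predictions_{practice}.csv",
        )
        log["practices"][practice] = {"n_predicted": int(len(preds))}
    _append_log(config, log)
    return log


def stage_classify(config: PipelineConfig) -> dict:
    """Terciles x rate intervals -> bivariate cost-efficiency classes."""
    tables = {"sequestration": read_input_table(config.paths["sequestration"], "sequestration")}
    geometry = None
    if "geometry" in config.paths:
        geometry = read_input_table(config.paths["geometry"], "geometry_stub")
    log: dict = {"stage": "classify", "practices": {}}
    for practice in config.practices:
        preds = pd.read_csv(config.out / f"predictions_{practice}.csv").set_index("county_id")
        seq = T.mean_sequestration(tables["sequestration"], practice)
        out = T.export_classification(
            preds["predicted_log_ratio"],
            seq,
            practice,
            out_path=config.out / f"classification_{practice}.csv",
            geometry_stub=geometry,
        )
        counts = out["class_code"].value_counts(dropna=True)
        log["practices"][practice] = {
            "n_classified": int(out["class_code"].notna().sum()),
            "n_missing": int(out["class_code"].isna().sum()),
            "class_counts": {str(k): int(v) for k, v in sorted(counts.items())},
        }
    _append_log(config, log)
    return log


def run_pipeline(config: PipelineConfig) -> dict:
    """Run features -> train -> predict (-> classify); returns the stage logs."""
    config.out.mkdir(parents=True, exist_ok=True)
    (config.out / "run_log.jsonl").write_text("")  # fresh log per run
    logs = [stage_features(config), stage_train(config), stage_predict(config)]
    if config.classify:
        logs.append(stage_classify(config))
    summary = {log["stage"]: log for log in logs}
    (config.out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    return summary


def _append_log(config: PipelineConfig, entry: dict) -> None:
    config.out.mkdir(parents=True, exist_ok=True)
    with open(config.out / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
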