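"""Honest regression forest for county-level adoption-rate forecasting.

Each tree is grown on a without-replacement subsample of the training rows.
The subsample is split into two disjoint halves: a *split half* used to
choose the recursive partitioning, and an *estimation half* whose outcomes
alone populate the leaf means.  This "honesty" decouples where the tree
splits from what it predicts, which removes the overfitting bias that makes
ordinary forest leaf means too extreme.

Splitting contract: at each node, ``mtry`` predictors are drawn at random;
the chosen split maximises the variance reduction on the split half minus
``imbalance_penalty * (1/n_left + 1/n_right)``, subject to each child
receiving at least ``alpha`` of the node's split-half points and each child
holding at least ``min_node_size`` estimation-half points.

Out-of-bag (OOB) predictions for a training row average the leaf means of
only those trees whose subsample excluded the row; they feed the
calibration test (regression of outcomes on the mean prediction and the
demeaned per-row prediction; both coefficients near 1 for a well-calibrated
forest).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "ForestModel",
    "CalibrationResult",
    "TILLAGE_FOREST_CONFIG",
    "COVER_CROP_FOREST_CONFIG",
    "build_target",
    "fit_honest_forest",
    "predict_forest",
    "oob_predict",
    "split_importance",
    "iterative_train",
    "calibration_test",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``sample_fraction`` — per-tree subsample size as a fraction of n (drawn
    without replacement); ``mtry`` — predictors considered per split;
    ``min_node_size`` — minimum estimation-half points per leaf; ``alpha``
    — minimum fraction of a node's split-half points each child must
    receive; ``imbalance_penalty`` — penalty scale on (1/n_left +
    1/n_right); ``honesty_fraction`` — fraction of the subsample used for
    split selection (the rest estimates leaf means).
    """

    num_trees: int = 2000
    sample_fraction: float = 0.5
    mtry: int = 10
    min_node_size: int = 5
    alpha: float = 0.05
    imbalance_penalty: float = 0.0
    honesty_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if not 0 < self.honesty_fraction < 1:
            raise ValueError("honesty_fraction must be in (0, 1)")
        if not 0 <= self.alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        if self.min_node_size < 1 or self.num_trees < 1 or self.mtry < 1:
            raise ValueError("num_trees, mtry and min_node_size must be positive")
        if self.imbalance_penalty < 0:
            raise ValueError("imbalance_penalty must be non-negative")


# Reference configurations for the two practices (num_trees 2000; 80% of
# each subsample selects splits, 20% estimates leaf means).
TILLAGE_FOREST_CONFIG = ForestConfig(
    sample_fraction=0.38, mtry=10, min_node_size=3, alpha=0.08, imbalance_penalty=0.72
)
COVER_CROP_FOREST_CONFIG = ForestConfig(
    sample_fraction=0.45, mtry=7, min_node_size=7, alpha=0.14, imbalance_penalty=0.36
)


@dataclass
class _Tree:
    feature: np.ndarray  # -1 for leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    depth: np.ndarray
    subsample: np.ndarray  # training-row indices in this tree's subsample
    split_half: np.ndarray  # indices used for split selection
    est_half: np.ndarray  # indices whose y populate leaf means

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for every row (vectorised level-by-level descent)."""
        node = np.zeros(len(X), dtype=np.int32)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return node


@dataclass
class ForestModel:
    """A fitted honest forest plus the bookkeeping needed for OOB work."""

    trees: list[_Tree]
    config: ForestConfig
    feature_names: list[str]
    n_train: int
    train_medians: pd.Series
    indicator_cols: list[str]
    inbag: np.ndarray = field(repr=False)  # (num_trees, n_train) bool

    def save(self, out_dir: str | Path) -> None:
        """Persist as a manifest plus flat node/membership tables (CSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        member_rows = []
        for t_id, tree in enumerate(self.trees):
            for n_id in range(len(tree.feature)):
                rows.append(
                    (t_id, n_id, int(tree.feature[n_id]), float(tree.threshold[n_id]),
                     int(tree.left[n_id]), int(tree.right[n_id]),
                     float(tree.value[n_id]), int(tree.depth[n_id]))
                )
            for r in tree.split_half:
                member_rows.append((t_id, int(r), "split"))
            for r in tree.est_half:
                member_rows.append((t_id, int(r), "estimate"))
        pd.DataFrame(
            rows,
            columns=["tree", "node", "feature", "threshold", "left", "right", "value", "depth"],
        ).to_csv(out / "nodes.csv", index=False)
        pd.DataFrame(member_rows, columns=["tree", "row", "half"]).to_csv(
            out / "membership.csv", index=False
        )
        manifest = {
            "config": self.config.__dict__,
            "feature_names": self.feature_names,
            "n_train": self.n_train,
            "train_medians": {k: float(v) for k, v in self.train_medians.items()},
            "indicator_cols": self.indicator_cols,
        }
        (out / "model.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ForestModel":
        src = Path(in_dir)
        manifest = json.loads((src / "model.json").read_text())
        nodes = pd.read_csv(src / "nodes.csv")
        members = pd.read_csv(src / "membership.csv")
        config = ForestConfig(**manifest["config"])
        n_train = manifest["n_train"]
        trees: list[_Tree] = []
        inbag = np.zeros((config.num_trees, n_train), dtype=bool)
        for t_id, grp in nodes.groupby("tree"):
            grp = grp.sort_values("node")
            mem = members[members["tree"] == t_id]
            split_half = mem.loc[mem["half"] == "split", "row"].to_numpy()
            est_half = mem.loc[mem["half"] == "estimate", "row"].to_numpy()
            subsample = np.concatenate([split_half, est_half])
            trees.append(
                _Tree(
                    feature=grp["feature"].to_numpy(np.int32),
                    threshold=grp["threshold"].to_numpy(float),
                    left=grp["left"].to_numpy(np.int32),
                    right=grp["right"].to_numpy(np.int32),
                    value=grp["value"].to_numpy(float),
                    depth=grp["depth"].to_numpy(np.int32),
                    subsample=subsample,
                    split_half=split_half,
                    est_half=est_half,
                )
            )
            inbag[t_id, subsample] = True
        return cls(
            trees=trees,
            config=config,
            feature_names=manifest["feature_names"],
            n_train=n_train,
            train_medians=pd.Series(manifest["train_medians"]),
            indicator_cols=manifest["indicator_cols"],
            inbag=inbag,
        )


def build_target(y_t: float | np.ndarray, y_prev: float | np.ndarray) -> float | np.ndarray:
    """Log acreage ratio ln(y_t / y_prev); inputs must be strictly positive."""
    y_t = np.asarray(y_t, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    if np.any(y_t <= 0) or np.any(y_prev <= 0):
        raise ValueError("build_target requires strictly positive acreages")
    out = np.log(y_t / y_prev)
    return float(out) if out.ndim == 0 else out


def _prepare_training(X: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.Series, list[str]]:
    """Median-impute missing cells and add companion missingness indicators."""
    X = X.copy()
    medians = X.median(numeric_only=True)
    indicator_cols = [c for c in X.columns if X[c].isna().any()]
    for c in indicator_cols:
        X[f"{c}_missing"] = X[c].isna().astype(float)
        X[c] = X[c].fillna(medians[c])
    return X.to_numpy(dtype=float), list(X.columns), medians, indicator_cols


def _prepare_prediction(
    X: pd.DataFrame, model: "ForestModel"
) -> np.ndarray:
    X = X.copy()
    for c in model.indicator_cols:
        X[f"{c}_missing"] = X[c].isna().astype(float)
        X[c] = X[c].fillna(model.train_medians[c])
    # any residual missing cells in non-indicator columns: impute, warn
    still = [c for c in X.columns if X[c].isna().any()]
    if still:
        logger.warning("imputing training medians for unexpected missing cells in %s", still)
        for c in still:
            X[c] = X[c].fillna(model.train_medians.get(c, 0.0))
    missing_cols = set(model.feature_names) - set(X.columns)
    if missing_cols:
        raise KeyError(f"prediction matrix lacks columns {sorted(missing_cols)}")
    return X[model.feature_names].to_numpy(dtype=float)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    split_idx: np.ndarray,
    est_idx: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
) -> _Tree:
    p = X.shape[1]
    mtry = min(config.mtry, p)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    depth_l: list[int] = []

    fallback_value = float(y[est_idx].mean()) if len(est_idx) else float(y[split_idx].mean())

    def new_node(depth: int) -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        depth_l.append(depth)
        return len(feature) - 1

    def best_split(s_idx: np.ndarray, e_idx: np.ndarray):
        n_s = len(s_idx)
        min_child = max(1, math.ceil(config.alpha * n_s))
        ys = y[s_idx]
        total_sum = ys.sum()
        best = None  # (score, feat, thr)
        for f in rng.choice(p, size=mtry, replace=False):
            xv = X[s_idx, f]
            order = np.argsort(xv, kind="stable")
            xs = xv[order]
            yo = ys[order]
            distinct = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # split positions
            if len(distinct) == 0:
                continue
            ok = (distinct >= min_child) & (n_s - distinct >= min_child)
            pos = distinct[ok]
            if len(pos) == 0:
                continue
            thr = (xs[pos - 1] + xs[pos]) / 2.0
            # estimation-half counts per candidate threshold
            ev = np.sort(X[e_idx, f])
            e_left = np.searchsorted(ev, thr, side="right")
            ok_e = (e_left >= config.min_node_size) & (
                len(ev) - e_left >= config.min_node_size
            )
            pos = pos[ok_e]
            thr = thr[ok_e]
            if len(pos) == 0:
                continue
            csum = np.cumsum(yo)
            sl = csum[pos - 1]
            nl = pos.astype(float)
            nr = n_s - nl
            # gain in sum of n*mean^2 == decrease in within-node SSE
            gain = sl**2 / nl + (total_sum - sl) ** 2 / nr - total_sum**2 / n_s
            score = gain - config.imbalance_penalty * (1.0 / nl + 1.0 / nr)
            j = int(np.argmax(score))
            if best is None or score[j] > best[0]:
                best = (float(score[j]), int(f), float(thr[j]))
        return best

    def grow(s_idx: np.ndarray, e_idx: np.ndarray, depth: int) -> int:
        node = new_node(depth)
        can_split = (
            len(s_idx) >= 2
            and len(e_idx) >= 2 * config.min_node_size
            and np.ptp(y[s_idx]) > 0
        )
        choice = best_split(s_idx, e_idx) if can_split else None
        if choice is None or choice[0] <= 0:
            value[node] = float(y[e_idx].mean()) if len(e_idx) else fallback_value
            return node
        _, f, thr = choice
        feature[node] = f
        threshold[node] = thr
        s_go = X[s_idx, f] <= thr
        e_go = X[e_idx, f] <= thr
        left[node] = grow(s_idx[s_go], e_idx[e_go], depth + 1)
        right[node] = grow(s_idx[~s_go], e_idx[~e_go], depth + 1)
        return node

    grow(split_idx, est_idx, 1)
    return _Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=np.asarray(value, dtype=float),
        depth=np.asarray(depth_l, dtype=np.int32),
        subsample=np.concatenate([split_idx, est_idx]),
        split_half=split_idx,
        est_half=est_idx,
    )


def fit_honest_forest(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: ForestConfig
) -> ForestModel:
    """Fit an honest regression forest; deterministic for a fixed seed.

    Missing predictor cells are median-imputed (training medians) with a
    companion missingness-indicator column appended per affected predictor.
    Raises before fitting if the subsample is too small for the honesty
    split and ``min_node_size`` to be satisfiable at the root.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.isnan(y_arr).any():
        raise ValueError("targets must not contain missing values")
    X_arr, names, medians, indicator_cols = _prepare_training(X)
    n = len(X_arr)
    s = max(2, int(round(config.sample_fraction * n)))
    n_split = max(1, int(round(config.honesty_fraction * s)))
    n_est = s - n_split
    if n_est < config.min_node_size:
        raise ValueError(
            f"subsample of {s} leaves only {n_est} estimation rows; "
            f"min_node_size={config.min_node_size} is unattainable"
        )

    rng = np.random.default_rng(config.seed)
    trees: list[_Tree] = []
    inbag = np.zeros((config.num_trees, n), dtype=bool)
    for t in range(config.num_trees):
        sub = rng.choice(n, size=s, replace=False)
        perm = rng.permutation(s)
        split_idx = sub[perm[:n_split]]
        est_idx = sub[perm[n_split:]]
        tree = _grow_tree(X_arr, y_arr, split_idx, est_idx, config, rng)
        trees.append(tree)
        inbag[t, sub] = True
    return ForestModel(
        trees=trees,
        config=config,
        feature_names=names,
        n_train=n,
        train_medians=medians,
        indicator_cols=indicator_cols,
        inbag=inbag,
    )


def predict_forest(model: ForestModel, X: pd.DataFrame) -> np.ndarray:
    """Forest prediction: mean over trees of the containing leaf's honest mean."""
    X_arr = _prepare_prediction(X, model)
    preds = np.zeros(len(X_arr))
    for tree in model.trees:
        leaves = tree.apply(X_arr)
        preds += tree.value[leaves]
    return preds / len(model.trees)


def oob_predict(
    model: ForestModel, X: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag predictions on the training rows.

    For each row, only trees whose subsample excluded that row contribute.
    Returns (predictions, n_oob_trees); rows covered by no tree get NaN.
    ``X`` must be the training design matrix in training row order.
    """
    if len(X) != model.n_train:
        raise ValueError("oob_predict requires the training matrix")
    X_arr = _prepare_prediction(X, model)
    total = np.zeros(model.n_train)
    count = np.zeros(model.n_train)
    for t, tree in enumerate(model.trees):
        leaves = tree.apply(X_arr)
        out_mask = ~model.inbag[t]
        total[out_mask] += tree.value[leaves[out_mask]]
        count[out_mask] += 1
    with np.errstate(invalid="ignore"):
        preds = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    n_missing = int((count == 0).sum())
    if n_missing:
        logger.warning("%d training rows have no out-of-bag tree", n_missing)
    return preds, count.astype(int)


def split_importance(model: ForestModel, max_depth: int = 4) -> pd.Series:
    """Depth-weighted split-frequency importance, normalised to sum 1.

    Each split at depth d (root = 1) contributes weight 1/d, counted over
    the top ``max_depth`` levels.  A forest with no splits returns zeros.
    """
    weights = np.zeros(len(model.feature_names))
    for tree in model.trees:
        internal = tree.feature >= 0
        shallow = internal & (tree.depth <= max_depth)
        np.add.at(weights, tree.feature[shallow], 1.0 / tree.depth[shallow])
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return pd.Series(weights, index=model.feature_names, name="importance")


def iterative_train(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: ForestConfig
) -> tuple[list[str], ForestModel, ForestModel]:
    """Two-stage fit: train on all predictors, refit on the most-used ones.

    Stage 1 fits on all p predictors; predictors with split-frequency
    importance >= 1/p are retained (if none clear the bar, the top
    ceil(p/4) are kept with a warning).  Stage 2 refits on the retained
    set with a fresh seed offset and mtry capped at the reduced width.
    Returns (selected predictor names, final model, stage-1 model).
    """
    stage1 = fit_honest_forest(X, y, config)
    imp = split_importance(stage1)
    # importance counts indicator companions toward their parent predictor
    base_imp = pd.Series(0.0, index=X.columns)
    for name, v in imp.items():
        base = name.removesuffix("_missing") if name.endswith("_missing") else name
        if base in base_imp.index:
            base_imp[base] += v
    p = X.shape[1]
    selected = list(base_imp.index[base_imp >= 1.0 / p])
    if not selected:
        k = math.ceil(p / 4)
        selected = list(base_imp.sort_values(ascending=False, kind="stable").index[:k])
        logger.warning("no predictor reached importance 1/p; falling back to top %d", k)
    logger.info("stage 1 retained %d of %d predictors: %s", len(selected), p, selected)
    cfg2 = replace(config, seed=config.seed + 1, mtry=min(config.mtry, len(selected)))
    stage2 = fit_honest_forest(X[selected], y, cfg2)
    return selected, stage2, stage1


@dataclass(frozen=True)
class CalibrationResult:
    """Mean/differential forest-prediction calibration test on OOB data.

    ``mean_pred_coef`` near 1 means the average prediction level is right;
    ``diff_pred_coef`` near 1 means prediction heterogeneity tracks outcome
    heterogeneity one-for-one.  One-sided p-values test coefficient > 0.
    """

    mean_pred_coef: float
    diff_pred_coef: float
    mean_pred_se: float
    diff_pred_se: float
    mean_pred_t: float
    diff_pred_t: float
    mean_pred_p: float
    diff_pred_p: float
    n_oob: int
    degenerate: bool = False


def calibration_test(
    oob_predictions: np.ndarray, y: np.ndarray | pd.Series
) -> CalibrationResult:
    """OLS of y on (mean OOB prediction, demeaned OOB prediction), no intercept.

    Heteroskedasticity-robust (HC3) standard errors; one-sided p-values for
    the hypothesis that each coefficient exceeds zero.  Requires at least
    10 rows with a defined OOB prediction.  If the OOB predictions have
    zero variance the differential coefficient is undefined (NaN, flagged).
    """
    import statsmodels.api as sm

    oob = np.asarray(oob_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(oob) & ~np.isnan(y)
    oob, y = oob[ok], y[ok]
    if len(oob) < 10:
        raise ValueError(f"need >= 10 OOB predictions, have {len(oob)}")
    mean_pred = oob.mean()
    centered = oob - mean_pred
    if np.allclose(centered, 0.0):
        const = np.full_like(y, mean_pred)
        fit = sm.OLS(y, const[:, None]).fit(cov_type="HC3")
        t1 = float(fit.tvalues[0])
        return CalibrationResult(
            mean_pred_coef=float(fit.params[0]),
            diff_pred_coef=math.nan,
            mean_pred_se=float(fit.bse[0]),
            diff_pred_se=math.nan,
            mean_pred_t=t1,
            diff_pred_t=math.nan,
            mean_pred_p=float(stats.t.sf(t1, df=fit.df_resid)),
            diff_pred_p=math.nan,
            n_oob=len(y),
            degenerate=True,
        )
    design = np.column_stack([np.full_like(y, mean_pred), centered])
    fit = sm.OLS(y, design).fit(cov_type="HC3")
    t = fit.tvalues
    p_one_sided = stats.t.sf(t, df=fit.df_resid)
    return CalibrationResult(
        mean_pred_coef=float(fit.params[0]),
        diff_pred_coef=float(fit.params[1]),
        mean_pred_se=float(fit.bse[0]),
        diff_pred_se=float(fit.bse[1]),
        mean_pred_t=float(t[0]),
        diff_pred_t=float(t[1]),
        mean_pred_p=float(p_one_sided[0]),
        diff_pred_p=float(p_one_sided[1]),
        n_oob=len(y),
    )
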