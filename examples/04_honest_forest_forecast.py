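"""Forecast county adoption growth with an honest regression forest.

Fits the two-stage (iterative variable selection) honest forest on the
wave-1 -> wave-2 log acreage ratio of a synthetic 500-county panel, runs
the out-of-bag calibration test, and scores next-wave predictions against
the held-out third census wave.
"""

import numpy as np
from scipy.stats import spearmanr

from agtarget.forest import (
    ForestConfig,
    calibration_test,
    iterative_train,
    oob_predict,
    predict_forest,
)
from agtarget.synthdata import make_forest_fixture

X, y, X_future, y_future = make_forest_fixture(n_counties=500, n_predictors=20, seed=7)
config = ForestConfig(
    num_trees=200, sample_fraction=0.45, mtry=7, min_node_size=7,
    alpha=0.14, imbalance_penalty=0.36, honesty_fraction=0.8, seed=11,
)

selected, model, stage1 = iterative_train(X, y, config)
print(f"stage 1 kept {len(selected)}/{X.shape[1]} predictors: {selected}")

oob, n_oob = oob_predict(model, X[selected])
cal = calibration_test(oob, y)
print(f"calibration: mean-prediction coef {cal.mean_pred_coef:.3f} "
      f"(se {cal.mean_pred_se:.3f}), differential coef {cal.diff_pred_coef:.3f} "
      f"(se {cal.diff_pred_se:.3f}) on {cal.n_oob} OOB rows")

preds = predict_forest(model, X_future[selected])
rho, p = spearmanr(preds, y_future)
print(f"held-out wave: Spearman rho {rho:.3f} (p = {p:.2e}); "
      f"{(preds <= 0).mean():.0%} of counties predicted to lose acreage")
print()
print(
    "Coefficients near 1 say the forest's average level and its\n"
    "heterogeneity are both trustworthy; the positive rank correlation with\n"
    "the never-seen third wave shows the forecast transfers forward."
)
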