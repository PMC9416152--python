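"""Fit one presence/absence forest by hand and read its diagnostics.

A 40-sample toy problem with one informative predictor among 20: the
out-of-bag (OOB) balanced accuracy estimates how well presence can be
predicted without a held-out set, and the mean decrease in Gini ranks
predictors by the impurity reduction their splits achieve.
"""

import numpy as np

from metabotu import ForestParams, fit_random_forest, mean_decrease_gini, oob_predict
from metabotu.pipeline import balanced_accuracy

rng = np.random.default_rng(0)
X = rng.normal(size=(40, 20))
logit = 4.0 * X[:, 7]
y = (rng.random(40) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

model = fit_random_forest(X, y, ForestParams(n_trees=500, seed=1))
pred = oob_predict(model)
print(f"classes: {int(y.sum())} present / {int(40 - y.sum())} absent")
print(f"OOB balanced accuracy: {balanced_accuracy(y, pred):.3f}")

importance = mean_decrease_gini(model)
top = sorted(importance, key=importance.get, reverse=True)[:5]
print("top predictors by mean decrease in Gini "
      "(predictor 7 carries the planted signal):")
for j in top:
    print(f"  predictor {j:2d}: {importance[j]:.3f}")
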