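"""Self-contained random forest for binary presence/absence classification.

Implements bootstrap-aggregated CART-style trees with Gini splitting,
out-of-bag (OOB) voting and mean-decrease-in-Gini variable importance --
the classical classification forest of Breiman, specialised to two classes.
Each OTU model downstream is one of these forests with metabolites as
predictors.

Design notes
------------
* Determinism: a single master seed feeds a ``numpy.random.SeedSequence``
  whose spawned children drive each tree, so the forest is reproducible
  and independent of tree execution order.
* Predictor identity: candidate-predictor sampling and tie-breaking are
  performed on *sorted predictor IDs*, not on column positions, so a
  forest is invariant to reordering of the input columns.
* Split search: thresholds are midpoints between consecutive distinct
  sorted values; the split maximising the (count-weighted) Gini decrease
  n_t G(t) - n_L G(L) - n_R G(R) is chosen, ties broken by lowest
  predictor ID then lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np

from .containers import ConfigError, InsufficientDataError

__all__ = [
    "ForestParams",
    "ForestModel",
    "gini_impurity",
    "grow_tree",
    "fit_random_forest",
    "oob_predict",
    "mean_decrease_gini",
]


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters of the classification forest.

    Defaults follow the standard classification-forest conventions:
    500 trees, mtry = floor(sqrt(p)), minimum node size 1, and full-size
    bootstrap samples drawn with replacement.
    """

    n_trees: int = 500
    mtry: int | None = None  # default floor(sqrt(#predictors)) at fit time
    min_node_size: int = 1
    bootstrap_size: int | None = None  # default n samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ConfigError("min_node_size must be >= 1")

    def resolve_mtry(self, n_predictors: int) -> int:
        m = self.mtry if self.mtry is not None else int(math.floor(math.sqrt(n_predictors)))
        m = max(1, m)
        if m > n_predictors:
            raise ConfigError(f"mtry={m} exceeds number of predictors {n_predictors}")
        return m


@dataclass
class Tree:
    """A fitted binary tree in flat-array form.

    ``feature[i]`` is the canonical predictor index split on at node i
    (-1 for leaves), ``threshold[i]`` the split point (go left iff
    x <= threshold), ``children[i]`` = (left, right) node ids, and
    ``leaf_class[i]`` the majority class at leaves.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    class_counts: np.ndarray  # node x 2 bagged class counts

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.intp)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return self.leaf_class[node]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "class_counts": self.class_counts.tolist(),
        }


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum((n_c / n)^2) of a two-class node."""
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise InsufficientDataError("empty node has no defined impurity")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _best_split(Xc, y, idx, cand, min_child):
    """Best (feature, threshold, decrease) over candidate predictors at a node.

    Returns (feat, thr, decrease, left_mask) or None if no admissible split.
    ``cand`` must be sorted ascending (canonical ID order) so that the
    first column attaining the maximum realises the lowest-ID tie-break.
    """
    m = idx.shape[0]
    Xs = Xc[np.ix_(idx, cand)]
    order = np.argsort(Xs, axis=0, kind="stable")
    Xsort = np.take_along_axis(Xs, order, axis=0)
    ysort = y[idx][order]

    n1 = int(y[idx].sum())
    n0 = m - n1
    parent = (n0 * n0 + n1 * n1) / m  # m * (1 - G(t)) up to sign

    # cumulative class-1 counts after each split position k (left size k+1)
    c1 = np.cumsum(ysort, axis=0)[:-1]  # (m-1) x ncand
    nL = np.arange(1, m, dtype=np.float64)[:, None]
    nR = m - nL
    c1 = c1.astype(np.float64)
    c0 = nL - c1
    r1 = n1 - c1
    r0 = nR - r1
    score = (c0 * c0 + c1 * c1) / nL + (r0 * r0 + r1 * r1) / nR
    # a split is only valid between strictly different values and when both
    # children meet the minimum node size
    valid = Xsort[:-1] < Xsort[1:]
    if min_child > 1:
        size_ok = (nL >= min_child) & (nR >= min_child)
        valid = valid & size_ok
    score = np.where(valid, score, -np.inf)

    flat = np.argmax(score.T)  # row-major over (cand, k): lowest ID, then lowest k
    best = score.T.flat[flat]
    if not np.isfinite(best):
        return None
    decrease = best - parent
    if decrease <= 1e-12:
        return None
    j, k = divmod(flat, m - 1)
    feat = int(cand[j])
    thr = float(0.5 * (Xsort[k, j] + Xsort[k + 1, j]))
    left_mask = Xc[idx, feat] <= thr
    return feat, thr, float(decrease), left_mask


def grow_tree(
    Xc: np.ndarray,
    y: np.ndarray,
    bag: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
    importance_out: np.ndarray | None = None,
) -> Tree:
    """Grow one CART tree on the bagged samples.

    ``Xc`` must already be in canonical (sorted-predictor-ID) column order;
    ``bag`` is a multiset of row indices (with repetition). If
    ``importance_out`` is given, each realised split adds its Gini decrease
    n_t*G(t) - n_L*G(L) - n_R*G(R) to ``importance_out[feature]``.
    """
    if bag.size == 0:
        raise InsufficientDataError("empty bootstrap bag")
    n_pred = Xc.shape[1]
    mtry = params.resolve_mtry(n_pred)
    all_pred = np.arange(n_pred)

    feature, threshold, left, right, leaf_class, counts = [], [], [], [], [], []
    stack = [(bag, -1, False)]  # (indices, parent node id, is_right_child)
    while stack:
        idx, parent, is_right = stack.pop()
        node_id = len(feature)
        if parent >= 0:
            (right if is_right else left)[parent] = node_id
        y_node = y[idx]
        m = idx.shape[0]
        n1 = int(y_node.sum())
        n0 = m - n1
        counts.append((n0, n1))

        split = None
        if n0 > 0 and n1 > 0 and m >= 2 * params.min_node_size and m >= 2:
            if mtry >= n_pred:
                cand = all_pred
            else:
                cand = np.sort(rng.choice(n_pred, size=mtry, replace=False))
            split = _best_split(Xc, y, idx, cand, params.min_node_size)

        if split is None:
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            # majority class; exact ties broken toward class 1 ("present")
            leaf_class.append(1 if n1 >= n0 else 0)
        else:
            feat, thr, decrease, left_mask = split
            if importance_out is not None:
                importance_out[feat] += decrease
            feature.append(feat)
            threshold.append(thr)
            left.append(-1)
            right.append(-1)
            leaf_class.append(-1)
            stack.append((idx[~left_mask], node_id, True))
            stack.append((idx[left_mask], node_id, False))

    return Tree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=np.float64),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        leaf_class=np.asarray(leaf_class, dtype=np.int8),
        class_counts=np.asarray(counts, dtype=np.int64),
    )


@dataclass
class ForestModel:
    """A fitted forest: trees, accumulated OOB votes and Gini importance."""

    trees: list
    params: ForestParams
    predictor_ids: list
    oob_votes: np.ndarray  # n_samples x 2 vote counts
    importance_raw: np.ndarray  # canonical order, summed over trees
    _canonical_order: np.ndarray = field(repr=False, default=None)

    def importance(self) -> dict:
        """Mean decrease in Gini per predictor ID (original input order)."""
        per_tree = self.importance_raw / self.params.n_trees
        # importance_raw is canonical-order; map back to input order
        canon_ids = [self.predictor_ids[i] for i in self._canonical_order]
        by_id = dict(zip(canon_ids, per_tree))
        return {pid: float(by_id[pid]) for pid in self.predictor_ids}

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {
                    "n_trees": self.params.n_trees,
                    "mtry": self.params.mtry,
                    "min_node_size": self.params.min_node_size,
                    "bootstrap_size": self.params.bootstrap_size,
                    "seed": self.params.seed,
                },
                "predictor_ids": list(map(str, self.predictor_ids)),
                "trees": [t.to_dict() for t in self.trees],
                "importance": {str(k): v for k, v in self.importance().items()},
            }
        )


def fit_random_forest(X, y, params: ForestParams, predictor_ids=None) -> ForestModel:
    """Fit a bagged Gini forest with OOB voting.

    Parameters
    ----------
    X : (n_samples, n_predictors) float array, complete (no missing values).
    y : binary labels (0 = absent, 1 = present), both classes represented
        by at least 2 samples.
    params : ForestParams
    predictor_ids : optional sequence of hashable predictor identifiers;
        defaults to 0..p-1. Candidate sampling and tie-breaking operate on
        the sorted-ID ordering, so column order does not affect the fit.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y).astype(np.int8)
    if np.isnan(X).any():
        raise ConfigError("predictors must be complete; impute missing values upstream")
    n, p = X.shape
    if predictor_ids is None:
        predictor_ids = list(range(p))
    predictor_ids = list(predictor_ids)
    if len(predictor_ids) != p:
        raise ConfigError("predictor_ids length must match number of predictors")
    classes, class_n = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientDataError("labels are single-class; the model is undefined")
    if class_n.min() < 2:
        raise InsufficientDataError("need >= 2 samples in each class")

    order = np.argsort(np.asarray(predictor_ids, dtype=object), kind="stable")
    Xc = np.ascontiguousarray(X[:, order])

    bag_size = params.bootstrap_size or n
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    trees = []
    oob_votes = np.zeros((n, 2), dtype=np.int64)
    importance = np.zeros(p, dtype=np.float64)
    sample_idx = np.arange(n)
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        bag = rng.integers(0, n, size=bag_size)
        tree = grow_tree(Xc, y, bag, params, rng, importance_out=importance)
        trees.append(tree)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[bag] = True
        oob = sample_idx[~in_bag]
        if oob.size:
            pred = tree.predict(Xc[oob])
            np.add.at(oob_votes, (oob, pred.astype(np.intp)), 1)

    return ForestModel(
        trees=trees,
        params=params,
        predictor_ids=predictor_ids,
        oob_votes=oob_votes,
        importance_raw=importance,
        _canonical_order=order,
    )


def oob_predict(model: ForestModel, tie_rule: str = "present") -> np.ndarray:
    """Per-sample OOB majority-vote labels.

    Ties are broken by ``tie_rule`` ("present" -> class 1, "absent" ->
    class 0). Samples that were never out-of-bag (possible only at very
    small n_trees) are returned as -1.
    """
    votes = model.oob_votes
    pred = np.full(votes.shape[0], -1, dtype=np.int8)
    has_votes = votes.sum(axis=1) > 0
    v0, v1 = votes[:, 0], votes[:, 1]
    tie_class = 1 if tie_rule == "present" else 0
    pred[has_votes] = np.where(
        v1[has_votes] > v0[has_votes],
        1,
        np.where(v1[has_votes] < v0[has_votes], 0, tie_class),
    )
    return pred


def mean_decrease_gini(model: ForestModel) -> dict:
    """Variable importance: total Gini decrease per predictor / n_trees."""
    return model.importance()
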