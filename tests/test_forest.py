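"""Forest engine: split search, OOB voting, Gini importance, determinism."""

import numpy as np
import pytest

from metabotu.containers import ConfigError, InsufficientDataError
from metabotu.forest import (
    ForestParams,
    fit_random_forest,
    gini_impurity,
    grow_tree,
    mean_decrease_gini,
    oob_predict,
)


def brute_force_best_split(X, y):
    """Exhaustive best (feature, threshold) by weighted Gini decrease.

    Ties broken by lowest feature index then lowest threshold, matching
    the documented convention. Returns None if no split decreases
    impurity.
    """
    n = len(y)
    n1 = int(np.sum(y))
    parent = n * gini_impurity((n - n1, n1))
    best = None
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = X[:, j] <= thr
            nl1 = int(np.sum(y[left]))
            nr1 = n1 - nl1
            nl, nr = int(left.sum()), int(n - left.sum())
            dec = (
                parent
                - nl * gini_impurity((nl - nl1, nl1))
                - nr * gini_impurity((nr - nr1, nr1))
            )
            if dec > 1e-12 and (best is None or dec > best[0] + 1e-12):
                best = (dec, j, thr)
    return best


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((3, 3), 0.5), ((4, 0), 0.0), ((1, 3), 0.375), ((0, 7), 0.0)]
    )
    def test_closed_form(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(InsufficientDataError):
            gini_impurity((0, 0))


class TestGrowTree:
    def grow(self, X, y, **kwargs):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int8)
        params = ForestParams(mtry=X.shape[1], **kwargs)
        rng = np.random.default_rng(0)
        imp = np.zeros(X.shape[1])
        tree = grow_tree(X, y, np.arange(len(y)), params, rng, importance_out=imp)
        return tree, imp

    def test_perfect_separator_gives_depth_one(self):
        X = np.array([[0.1], [0.2], [0.9], [1.0]])
        tree, _ = self.grow(X, [0, 0, 1, 1])
        assert (tree.feature >= 0).sum() == 1  # one internal node
        assert np.array_equal(tree.predict(X), [0, 0, 1, 1])

    def test_constant_predictors_single_leaf_majority(self):
        X = np.ones((5, 2))
        tree, _ = self.grow(X, [0, 1, 1, 1, 0])
        assert len(tree.feature) == 1 and tree.feature[0] == -1
        assert tree.leaf_class[0] == 1

    def test_pure_bag_single_leaf(self):
        tree, _ = self.grow(np.random.default_rng(1).random((4, 2)), [1, 1, 1, 1])
        assert len(tree.feature) == 1

    def test_single_split_importance_closed_form(self):
        # root (5,5) split into pure children: 10*0.5 - 0 - 0 = 5
        X = np.r_[np.zeros((5, 1)), np.ones((5, 1))]
        y = [0] * 5 + [1] * 5
        _, imp = self.grow(X, y)
        assert imp[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_root_split_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, 4))
        X = np.round(rng.random((n, p)), 2)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        tree, imp = self.grow(X, y)
        expected = brute_force_best_split(X, y.astype(np.int8))
        if expected is None:
            assert tree.feature[0] == -1
        else:
            dec, j, thr = expected
            assert tree.feature[0] == j
            assert tree.threshold[0] == pytest.approx(thr)

    def test_importance_conservation_single_tree(self):
        """Summed importance equals total impurity decrease over all nodes."""
        rng = np.random.default_rng(3)
        X = rng.random((30, 4))
        y = (X[:, 1] + 0.3 * rng.random(30) > 0.6).astype(np.int8)
        tree, imp = self.grow(X, y)
        total = 0.0
        for node in range(len(tree.feature)):
            if tree.feature[node] < 0:
                continue
            c = tree.class_counts
            t, l, r = c[node], c[tree.left[node]], c[tree.right[node]]
            total += (
                t.sum() * gini_impurity(t)
                - l.sum() * gini_impurity(l)
                - r.sum() * gini_impurity(r)
            )
        assert imp.sum() == pytest.approx(total)


class TestForest:
    def test_same_seed_identical_fit(self):
        rng = np.random.default_rng(0)
        X = rng.random((25, 6))
        y = (X[:, 0] > 0.5).astype(int)
        a = fit_random_forest(X, y, ForestParams(n_trees=40, seed=9))
        b = fit_random_forest(X, y, ForestParams(n_trees=40, seed=9))
        assert np.array_equal(a.oob_votes, b.oob_votes)
        assert np.allclose(a.importance_raw, b.importance_raw)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(InsufficientDataError):
            fit_random_forest(X, np.ones(10), ForestParams(n_trees=5))

    def test_missing_predictors_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ConfigError):
            fit_random_forest(X, [0, 1] * 5, ForestParams(n_trees=5))

    def test_perfect_predictor_high_oob_and_top_importance(self):
        """A predictor separating the classes with a margin yields near-perfect
        OOB balanced accuracy and maximal importance."""
        hits_ba, hits_top = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 5))
            y = rng.integers(0, 2, size=30)
            y[:2] = [0, 1]  # both classes present
            X[:, 2] = np.where(y == 1, 1, -1) * rng.uniform(0.2, 1.5, size=30)
            model = fit_random_forest(X, y, ForestParams(n_trees=500, seed=seed))
            pred = oob_predict(model)
            tpr = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
            tnr = ((pred == 0) & (y == 0)).sum() / (y == 0).sum()
            imp = mean_decrease_gini(model)
            hits_ba += (tpr + tnr) / 2 >= 0.95
            hits_top += max(imp, key=imp.get) == 2
        assert hits_ba == 20
        assert hits_top == 20

    def test_null_labels_oob_near_half(self):
        bas = []
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 8))
            y = np.repeat([0, 1], 30)
            model = fit_random_forest(X, y, ForestParams(n_trees=150, seed=seed))
            pred = oob_predict(model)
            tpr = ((pred == 1) & (y == 1)).sum() / 30
            tnr = ((pred == 0) & (y == 0)).sum() / 30
            bas.append((tpr + tnr) / 2)
        assert 0.4 <= np.mean(bas) <= 0.6

    def test_unused_predictor_zero_importance(self):
        rng = np.random.default_rng(1)
        X = np.c_[rng.normal(size=(20, 1)), np.full((20, 1), 3.14)]
        y = (X[:, 0] > 0).astype(int)
        model = fit_random_forest(X, y, ForestParams(n_trees=50, mtry=2, seed=0))
        assert mean_decrease_gini(model)[1] == 0.0
        assert min(mean_decrease_gini(model).values()) >= 0.0

    def test_predictor_reordering_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 7))
        y = (X[:, 3] + 0.5 * rng.normal(size=30) > 0).astype(int)
        ids = [f"m{j}" for j in range(7)]
        a = fit_random_forest(X, y, ForestParams(n_trees=60, seed=4), predictor_ids=ids)
        perm = rng.permutation(7)
        b = fit_random_forest(
            X[:, perm], y, ForestParams(n_trees=60, seed=4),
            predictor_ids=[ids[j] for j in perm],
        )
        assert np.array_equal(a.oob_votes, b.oob_votes)
        ia, ib = mean_decrease_gini(a), mean_decrease_gini(b)
        assert all(ia[k] == pytest.approx(ib[k]) for k in ids)

    def test_duplicated_informative_predictor_still_dominates(self):
        """Splitting credit between copies keeps one of them on top."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 6))
            y = (X[:, 0] > 0.1).astype(int)
            if y.sum() < 3 or y.sum() > 37:
                continue
            Xdup = np.c_[X, X[:, 0]]
            model = fit_random_forest(Xdup, y, ForestParams(n_trees=200, seed=seed))
            imp = mean_decrease_gini(model)
            order = sorted(imp, key=imp.get, reverse=True)
            wins += {0, 6} & set(order[:2]) != set()
        assert wins >= 18


class TestSerialization:
    def test_model_round_trips_to_json(self):
        import json

        rng = np.random.default_rng(0)
        X = rng.random((12, 3))
        y = np.array([0, 1] * 6)
        model = fit_random_forest(X, y, ForestParams(n_trees=5, seed=2),
                                  predictor_ids=["a", "b", "c"])
        payload = json.loads(model.to_json())
        assert payload["params"]["n_trees"] == 5
        assert payload["predictor_ids"] == ["a", "b", "c"]
        assert len(payload["trees"]) == 5
        assert set(payload["importance"]) == {"a", "b", "c"}


class TestOobPredict:
    def make_model(self, votes):
        class Stub:
            oob_votes = np.asarray(votes)
        return Stub()

    def test_majority(self):
        pred = oob_predict(self.make_model([[10, 2], [2, 10]]))
        assert pred.tolist() == [0, 1]

    def test_tie_rules(self):
        model = self.make_model([[5, 5]])
        assert oob_predict(model, tie_rule="present")[0] == 1
        assert oob_predict(model, tie_rule="absent")[0] == 0

    def test_zero_votes_flagged(self):
        assert oob_predict(self.make_model([[0, 0]]))[0] == -1

    def test_everyone_votes_at_realistic_tree_counts(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        y = ([0, 1] * 10)
        model = fit_random_forest(X, np.array(y), ForestParams(n_trees=100, seed=1))
        assert (model.oob_votes.sum(axis=1) > 0).all()


class TestCrossCheckAgainstSklearn:
    def test_informative_predictor_agreement(self):
        """Independent ensemble implementation agrees on the top predictor
        and roughly on OOB error across seeded datasets."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        agree = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(50, 10))
            y = ((X[:, 4] + 0.5 * rng.normal(size=50)) > 0).astype(int)
            mine = fit_random_forest(X, y, ForestParams(n_trees=200, seed=seed))
            imp = mean_decrease_gini(mine)
            my_top = max(imp, key=imp.get)
            ref = sklearn.RandomForestClassifier(
                n_estimators=200, oob_score=True, random_state=seed
            ).fit(X, y)
            ref_top = int(np.argmax(ref.feature_importances_))
            pred = oob_predict(mine)
            my_err = float(np.mean(pred != y))
            ref_err = float(np.mean(ref.oob_decision_function_.argmax(1) != y))
            agree += (my_top == 4) and (ref_top == 4) and abs(my_err - ref_err) < 0.15
        assert agree / runs >= 0.95
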