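"""Regression trees/forest: split optimality, importances, metrics.

The reference for split choice and importance values is the naive
enumerator in ``oracle_forest``; scikit-learn appears only as an external
cross-check of the importance *ranking* on well-separated features.
"""

import math

import numpy as np
import pytest

import wqsource as wq
from wqsource.forest import TreeParams, fit_tree

import oracle_forest as oracle


def full_params():
    # deterministic exhaustive search: every feature tried at every node
    return TreeParams(max_features=None)


def make_tree(X, y):
    X = np.asarray(X, float)
    return fit_tree(X, np.asarray(y, float),
                    params=TreeParams(max_features=X.shape[1]))


def collect_impl_splits(node, out=None):
    if out is None:
        out = []
    if not node.is_leaf:
        out.append((node.feature, node.threshold))
        collect_impl_splits(node.left, out)
        collect_impl_splits(node.right, out)
    return out


class TestTreeGrowth:
    def test_constant_response_yields_single_leaf(self):
        tree = make_tree([[1.0], [2.0], [3.0]], [5.0, 5.0, 5.0])
        assert tree.root.is_leaf and tree.root.value == 5.0

    def test_first_split_falls_in_the_wide_gap(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = make_tree(X, y)
        assert 2.0 < tree.root.threshold < 10.0
        # the oracle agrees on the exact midpoint
        f, thr = oracle.best_split(X, y)
        assert (tree.root.feature, tree.root.threshold) == (f, thr)

    def test_leaves_predict_training_means(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        tree = make_tree(X, y)
        # training prediction at each sample equals its leaf's training mean
        pred = tree.predict(X)
        for leaf_value in np.unique(pred):
            members = y[pred == leaf_value]
            assert leaf_value == pytest.approx(members.mean())

    @pytest.mark.parametrize("n,m,seed", [
        (n, m, seed) for n in (2, 3, 4, 5, 6, 7, 8) for m in (1, 2, 3) for seed in (0, 1)
    ])
    def test_every_split_matches_brute_force(self, n, m, seed):
        rng = np.random.default_rng(1000 * n + 100 * m + seed)
        # small integer grids force duplicate values and exact score ties
        X = rng.integers(0, 4, size=(n, m)).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        tree = make_tree(X, y)
        ref = oracle.grow_tree(X, y)
        assert collect_impl_splits(tree.root) == oracle.collect_splits(ref)

    def test_tie_breaks_prefer_lowest_feature_then_threshold(self):
        # identical columns: both features give identical scores everywhere
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = make_tree(X, y)
        assert tree.root.feature == 0
        assert tree.root.threshold == pytest.approx(1.5)


class TestImportance:
    def test_single_split_owns_all_importance(self):
        X = np.array([[0.0, 7.0], [1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = make_tree(X, y)
        imp = tree.raw_importance()
        assert imp is not None
        assert imp[0] == pytest.approx(1.0) and imp[1] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_importances_match_brute_force_walker(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(4, 9), rng.integers(1, 4)
        X = rng.integers(0, 5, size=(n, m)).astype(float)
        y = rng.normal(size=n).round(2)
        tree = make_tree(X, y)
        ref = oracle.grow_tree(X, y)
        ref_imp = oracle.tree_importance(ref, n, m)
        imp = tree.raw_importance()
        if ref_imp is None:
            assert imp is None
        else:
            np.testing.assert_allclose(imp, ref_imp, atol=1e-12)

    def test_importance_sums_to_one(self, study_dataset, specs):
        table = wq.compute_wqi_table(study_dataset.values, specs)
        X = study_dataset.values.to_numpy()
        forest = wq.fit_forest(X, table["WQI"].to_numpy(), n_trees=15, seed=4)
        imp = wq.feature_importance(forest)
        assert imp.defined
        assert imp.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(imp.values >= 0)

    def test_telescoping_conservation_per_tree(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        tree = make_tree(X, y)
        total = sum(
            (nd.n_samples * nd.impurity
             - nd.left.n_samples * nd.left.impurity
             - nd.right.n_samples * nd.right.impurity) / tree.n_train
            for nd in tree.internal_nodes()
        )
        leaves_term = 0.0
        stack = [tree.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                leaves_term += nd.n_samples * nd.impurity / tree.n_train
            else:
                stack.extend([nd.left, nd.right])
        assert total == pytest.approx(tree.root.impurity - leaves_term, abs=1e-10)

    def test_all_leaf_forest_flagged_undefined(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([4.0, 4.0, 4.0])
        forest = wq.fit_forest(X, y, n_trees=3, seed=0)
        imp = wq.feature_importance(forest)
        assert not imp.defined and np.all(imp.values == 0)

    def test_ranking_agrees_with_reference_mdi(self):
        sklearn = pytest.importorskip("sklearn.ensemble")
        rng = np.random.default_rng(21)
        n = 400
        X = rng.normal(size=(n, 5))
        y = 5.0 * X[:, 2] + 2.0 * X[:, 0] + 0.1 * rng.normal(size=n)
        forest = wq.fit_forest(X, y, n_trees=40, seed=3)
        ours = np.argsort(-wq.feature_importance(forest).values)[:2]
        ref = sklearn.RandomForestRegressor(n_estimators=40, random_state=0).fit(X, y)
        theirs = np.argsort(-ref.feature_importances_)[:2]
        assert list(ours) == list(theirs) == [2, 0]


class TestForest:
    def test_degenerate_ensemble_equals_single_tree(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + rng.normal(size=50)
        params = TreeParams(max_features=3)
        forest = wq.fit_forest(X, y, n_trees=1, params=params, seed=5, bootstrap=False)
        tree = forest.trees[0]
        np.testing.assert_array_equal(forest.predict(X), tree.predict(X))

    def test_same_seed_reproduces_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = X[:, 1] + rng.normal(size=60)
        a = wq.fit_forest(X, y, n_trees=8, seed=13).predict(X)
        b = wq.fit_forest(X, y, n_trees=8, seed=13).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_signal_beats_mean_predictor_out_of_sample(self):
        rng = np.random.default_rng(7)
        n = 500
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        y = 3.0 * X[:, 0] + 0.3 * rng.normal(size=n)
        train, test = wq.split_indices(n, 0.2, seed=1)
        forest = wq.fit_forest(X[train], y[train], n_trees=30, seed=2)
        m = wq.regression_metrics(y[test], forest.predict(X[test]))
        assert m.r2 > 0.5  # far above the mean-only predictor's 0

    def test_rejects_zero_trees(self):
        with pytest.raises(ValueError):
            wq.fit_forest(np.zeros((4, 1)), np.arange(4.0), n_trees=0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = wq.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.mse, m.mae, m.mape) == (1.0, 0.0, 0.0, 0.0)

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = wq.regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_mae_and_mape(self):
        m = wq.regression_metrics([100.0, 50.0], [90.0, 55.0])
        assert m.mae == pytest.approx(7.5)
        assert m.mape == pytest.approx(10.0)

    def test_zero_truth_flags_mape_undefined(self):
        m = wq.regression_metrics([0.0, 1.0], [0.5, 1.0])
        assert math.isnan(m.mape)
        assert m.mae == pytest.approx(0.25)
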