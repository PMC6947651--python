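"""Tree growth, sub-forest planning, forests, importance, prediction."""

import numpy as np
import pytest

import penirf as pf
from penirf.exceptions import DataError, ParameterError


def _tree_signature(tree):
    return (
        tree.feature.tobytes(),
        tree.threshold.tobytes(),
        tree.value.tobytes(),
        tree.left.tobytes(),
        tree.right.tobytes(),
    )


class TestGrowTree:
    def test_constant_target_yields_single_leaf(self):
        data = pf.Dataset(np.random.default_rng(0).standard_normal((30, 3)),
                          y=np.full(30, 7.0))
        tree = pf.grow_tree(data, tree_seed=1)
        assert tree.n_nodes == 1
        assert tree.root.is_leaf
        assert tree.root.prediction == pytest.approx(7.0)

    def test_same_seed_gives_identical_tree(self, linear_dataset):
        t1 = pf.grow_tree(linear_dataset, tree_seed=99)
        t2 = pf.grow_tree(linear_dataset, tree_seed=99)
        assert _tree_signature(t1) == _tree_signature(t2)

    def test_dominant_feature_wins_the_root(self, rng):
        X = rng.standard_normal((80, 2))
        data = pf.Dataset(X, y=X[:, 0].copy())
        for seed in range(5):
            tree = pf.grow_tree(data, mtry=2, min_node_size=1, tree_seed=seed)
            assert tree.root.split_feature == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            pf.grow_tree(pf.Dataset(np.empty((0, 0)), y=np.empty(0)), tree_seed=0)

    def test_children_partition_parent_samples(self, linear_dataset):
        tree = pf.grow_tree(linear_dataset, tree_seed=3)

        def check(node):
            if not node.is_leaf:
                assert node.left.n_samples + node.right.n_samples == node.n_samples
                assert node.impurity_decrease >= 0
                check(node.left)
                check(node.right)

        check(tree.root)


class TestPlanSubforests:
    def test_plan_is_independent_of_worker_count(self):
        assert pf.plan_subforests(10, 1, 7) == pf.plan_subforests(10, 5, 7)

    def test_seeds_are_distinct(self):
        seeds = [s for _, s in pf.plan_subforests(10, 1, 7)]
        assert len(set(seeds)) == 10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            pf.plan_subforests(0, 1, 7)
        with pytest.raises(ParameterError):
            pf.plan_subforests(5, 0, 7)


class TestGrowForest:
    def test_single_tree_forest_equals_grow_tree(self, linear_dataset):
        forest = pf.grow_forest(linear_dataset, n_trees=1, master_seed=5)
        seed = pf.plan_subforests(1, 1, 5)[0][1]
        tree = pf.grow_tree(linear_dataset, tree_seed=seed)
        assert _tree_signature(forest.trees[0]) == _tree_signature(tree)

    @pytest.mark.parametrize("n_workers", [2, 4])
    def test_worker_count_does_not_change_importance(self, linear_dataset, n_workers):
        ref = pf.grow_forest(linear_dataset, n_trees=24, master_seed=3, n_workers=1)
        alt = pf.grow_forest(linear_dataset, n_trees=24, master_seed=3,
                             n_workers=n_workers)
        assert np.array_equal(pf.impurity_importance(ref),
                              pf.impurity_importance(alt))

    def test_zero_weight_feature_is_never_split_on(self, linear_dataset):
        w = np.ones(10)
        w[4] = 0.0
        forest = pf.grow_forest(linear_dataset, weights=w, n_trees=40, master_seed=2)
        for tree in forest.trees:
            assert not np.any(tree.feature == 4)


class TestImportance:
    def test_leaf_only_forest_has_zero_importance(self):
        data = pf.Dataset(np.random.default_rng(1).standard_normal((30, 4)),
                          y=np.zeros(30))
        forest = pf.grow_forest(data, n_trees=10, master_seed=0)
        assert np.array_equal(pf.impurity_importance(forest), np.zeros(4))

    def test_planted_signal_ranks_first(self, rng):
        X = rng.standard_normal((150, 2))
        y = X[:, 0] + 0.0  # x1 is pure noise
        forest = pf.grow_forest(pf.Dataset(X, y=y), n_trees=200, mtry=1,
                                min_node_size=1, master_seed=8)
        imp = pf.impurity_importance(forest)
        assert imp[0] > imp[1]

    def test_column_permutation_permutes_importance(self, rng):
        X = rng.standard_normal((100, 5))
        y = X[:, 1] + 0.2 * rng.standard_normal(100)
        perm = np.array([3, 0, 4, 1, 2])
        base = pf.grow_forest(pf.Dataset(X, y=y), n_trees=60, master_seed=4)
        shuf = pf.grow_forest(pf.Dataset(X[:, perm], y=y), n_trees=60, master_seed=4)
        imp_base = pf.impurity_importance(base)
        imp_shuf = pf.impurity_importance(shuf)
        # the signal column dominates wherever it sits
        assert np.argmax(imp_base) == 1
        assert np.argmax(imp_shuf) == np.nonzero(perm == 1)[0][0]

    def test_total_importance_matches_tree_traversal(self, linear_dataset):
        forest = pf.grow_forest(linear_dataset, n_trees=30, master_seed=6)
        total = pf.impurity_importance(forest).sum()

        def node_sum(node):
            if node.is_leaf:
                return 0.0
            return (node.impurity_decrease + node_sum(node.left)
                    + node_sum(node.right))

        recomputed = sum(node_sum(t.root) for t in forest.trees) / forest.n_trees
        assert total == pytest.approx(recomputed, rel=1e-12)


class TestPredict:
    def test_constant_target_predicts_constant(self):
        data = pf.Dataset(np.random.default_rng(2).standard_normal((40, 3)),
                          y=np.full(40, 3.25))
        forest = pf.grow_forest(data, n_trees=5, master_seed=0)
        assert np.allclose(pf.predict(forest, data.X), 3.25)

    def test_training_fit_on_noiseless_signal(self, rng):
        X = np.linspace(-2, 2, 300).reshape(-1, 1)
        y = X[:, 0].copy()
        forest = pf.grow_forest(pf.Dataset(X, y=y), n_trees=200, mtry=1,
                                min_node_size=1, master_seed=1)
        pred = pf.predict(forest, X)
        assert 1 - np.mean((pred - y) ** 2) / np.var(y) > 0.9

    def test_column_mismatch_rejected(self, linear_dataset):
        forest = pf.grow_forest(linear_dataset, n_trees=3, master_seed=0)
        with pytest.raises(DataError):
            pf.predict(forest, np.zeros((5, 4)))


class TestEstimators:
    def test_regressor_follows_sklearn_conventions(self, rng):
        from sklearn.base import clone

        X = rng.standard_normal((100, 6))
        y = X[:, 2] + 0.1 * rng.standard_normal(100)
        est = pf.WeightedRandomForestRegressor(n_trees=50, random_state=0)
        est2 = clone(est)
        est.fit(X, y)
        assert est.n_features_in_ == 6
        assert np.argmax(est.feature_importances_) == 2
        assert est.score(X, y) > 0.5
        assert np.array_equal(
            est2.fit(X, y).feature_importances_, est.feature_importances_
        )

    def test_classifier_predicts_labels(self, rng):
        X = rng.standard_normal((120, 4))
        y = np.where(X[:, 0] > 0, "high", "low")
        est = pf.WeightedRandomForestClassifier(n_trees=60, random_state=1).fit(X, y)
        assert set(est.classes_) == {"high", "low"}
        assert (est.predict(X) == y).mean() > 0.9

    def test_pipeline_compatibility(self, rng):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        X = rng.standard_normal((80, 3))
        y = X[:, 0]
        pipe = make_pipeline(
            StandardScaler(), pf.WeightedRandomForestRegressor(n_trees=30)
        )
        assert pipe.fit(X, y).predict(X).shape == (80,)
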