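import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnnforest import (
    ClassDistribution,
    ForestParams,
    best_split,
    bootstrap_rows,
    build_forest,
    draw_split_candidate,
    gini_impurity,
    grow_tree,
    load_forest,
    max_candidate_features,
    predict_forest,
    predict_tree,
    save_forest,
)
from cnnforest.forest import DecisionTree, TreeNode, predict_forest_matrix


class TestGiniImpurity:
    def test_pure_node_is_zero(self):
        assert gini_impurity([4, 0]) == 0.0

    def test_balanced_binary_maximum(self):
        assert gini_impurity([2, 2]) == 0.5

    def test_three_one_split(self):
        assert gini_impurity([3, 1]) == pytest.approx(0.375)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassDistribution(np.array([-1, 2]))

    def test_exhaustive_brute_force_totals_up_to_50(self):
        # independent oracle: direct arithmetic over every binary distribution
        for total in range(1, 51):
            for k in range(total + 1):
                p0, p1 = k / total, (total - k) / total
                expected = 1.0 - (p0 * p0 + p1 * p1)
                assert gini_impurity([k, total - k]) == pytest.approx(expected, abs=1e-12)

    def test_monotone_toward_balance(self):
        for n in (10, 25, 47):
            values = [gini_impurity([k, n - k]) for k in range(n // 2 + 1)]
            assert all(b > a for a, b in zip(values, values[1:]))

    def test_range_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 30, size=2)
            if counts.sum() == 0:
                continue
            g = gini_impurity(counts)
            assert 0.0 <= g <= 0.5


class TestMaxCandidateFeatures:
    def test_thirty_six_gives_six(self):
        assert max_candidate_features(36) == 6

    def test_identity_floor(self):
        assert max_candidate_features(1) == 1

    def test_ceil_of_sqrt_ten(self):
        assert max_candidate_features(10) == 4

    def test_capped_at_n_features(self):
        assert max_candidate_features(2) == 2  # ceil(sqrt(2)) = 2

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            max_candidate_features(0)


class TestBootstrapRows:
    def test_single_row(self, rng):
        assert bootstrap_rows(1, rng).tolist() == [0]

    def test_length_and_range(self, rng):
        idx = bootstrap_rows(50, rng)
        assert len(idx) == 50
        assert idx.min() >= 0 and idx.max() < 50

    def test_deterministic_for_same_seed(self):
        a = bootstrap_rows(100, np.random.default_rng(5))
        b = bootstrap_rows(100, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_expected_distinct_fraction(self):
        # E[distinct]/n = 1 - (1 - 1/n)^n -> ~0.632; Monte-Carlo at n=1000
        rng = np.random.default_rng(12)
        n, draws = 1000, 1000
        fracs = [len(np.unique(bootstrap_rows(n, rng))) / n for _ in range(draws)]
        expected = 1.0 - (1.0 - 1.0 / n) ** n
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)


class TestDrawSplitCandidate:
    def test_singleton_matrix(self, rng):
        P = np.array([[0.7]])
        assert draw_split_candidate(P, np.array([0]), rng) == (0, 0.7)

    def test_constant_column_threshold(self, rng):
        P = np.full((10, 1), 0.3)
        for _ in range(20):
            col, thr = draw_split_candidate(P, np.arange(10), rng)
            assert (col, thr) == (0, 0.3)

    def test_empty_node_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_split_candidate(np.ones((3, 2)), np.array([], dtype=int), rng)

    def test_threshold_uniform_over_node_row_values(self):
        # chi-square vs the exact uniform pmf over (row, col) pairs
        from scipy.stats import chisquare

        rng = np.random.default_rng(99)
        P = np.arange(12, dtype=float).reshape(6, 2)  # all values distinct
        node_rows = np.arange(6)
        counts = {}
        n_draws = 10_000
        for _ in range(n_draws):
            col, thr = draw_split_candidate(P, node_rows, rng)
            counts[(col, thr)] = counts.get((col, thr), 0) + 1
        observed = [counts.get((c, float(P[r, c])), 0) for c in range(2) for r in range(6)]
        _, p = chisquare(observed)
        assert p > 0.01


def _brute_force_best(P, labels, rows):
    """Oracle: exhaustively score every (row, column) threshold pair."""
    best = np.inf
    for col in range(P.shape[1]):
        for r in rows:
            thr = P[r, col]
            left = rows[P[rows, col] <= thr]
            right = rows[P[rows, col] > thr]
            if len(left) == 0 or len(right) == 0:
                continue
            g = 0.0
            for part in (left, right):
                counts = np.bincount(labels[part], minlength=2)
                p = counts / counts.sum()
                g += len(part) * (1.0 - np.sum(p * p))
            best = min(best, g / len(rows))
    return None if best is np.inf else best


class TestBestSplit:
    def _weighted(self, P, labels, rows, col, thr):
        from cnnforest.forest import _weighted_child_gini

        return _weighted_child_gini(P, labels, rows, col, thr)

    def test_perfect_split_found_exhaustively(self, rng):
        P = np.array([[0.1], [0.2], [0.8], [0.9]])
        labels = np.array([0, 0, 1, 1])
        params = ForestParams(exhaustive=True)
        col, thr = best_split(P, labels, np.arange(4), params, rng)
        assert col == 0
        assert self._weighted(P, labels, np.arange(4), col, thr) == 0.0
        assert thr in (0.1, 0.2)  # only thresholds yielding gini 0 as left split

    def test_all_values_identical_gives_no_split(self, rng):
        P = np.full((6, 2), 0.5)
        labels = np.array([0, 1, 0, 1, 0, 1])
        assert best_split(P, labels, np.arange(6), ForestParams(), rng) is None

    def test_chosen_candidate_is_argmin_of_sampled(self):
        # replay the rng to recover the drawn candidates, then check argmin
        P = np.random.default_rng(3).random((30, 4))
        labels = (P[:, 0] > 0.5).astype(int)
        params = ForestParams(candidates_per_node=5)
        rows = np.arange(30)
        rng = np.random.default_rng(42)
        col, thr = best_split(P, labels, rows, params, rng)
        replay = np.random.default_rng(42)
        drawn = [draw_split_candidate(P, rows, replay) for _ in range(5)]
        chosen = self._weighted(P, labels, rows, col, thr)
        for c, t in drawn:
            score = self._weighted(P, labels, rows, c, t)
            if score is not None:
                assert chosen <= score + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(
        n_rows=st.integers(2, 20),
        n_cols=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_exhaustive_equals_brute_force_oracle(self, n_rows, n_cols, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((n_rows, n_cols))
        labels = rng.integers(0, 2, size=n_rows)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        rows = np.arange(n_rows)
        result = best_split(P, labels, rows, ForestParams(exhaustive=True), rng)
        oracle = _brute_force_best(P, labels, rows)
        if oracle is None:
            assert result is None
        else:
            col, thr = result
            assert self._weighted(P, labels, rows, col, thr) == pytest.approx(oracle)


class TestGrowTree:
    def test_pure_root_is_single_leaf(self, rng):
        P = np.random.default_rng(0).random((5, 2))
        labels = np.ones(5, dtype=int)
        tree = grow_tree(P, labels, ForestParams(bootstrap=False), rng)
        assert tree.root.is_leaf
        assert tree.root.predicted_class == 1

    def test_separable_1d_yields_depth_one_perfect_tree(self, rng):
        P = np.array([[0.1], [0.2], [0.8], [0.9]])
        labels = np.array([0, 0, 1, 1])
        params = ForestParams(bootstrap=False, exhaustive=True)
        tree = grow_tree(P, labels, params, rng)
        assert not tree.root.is_leaf
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert [predict_tree(tree, row) for row in P] == labels.tolist()

    def test_purity_contract_full_training_fit(self):
        # unique continuous features, exhaustive candidates, no bootstrap
        rng = np.random.default_rng(17)
        P = rng.random((40, 3))
        labels = rng.integers(0, 2, size=40)
        params = ForestParams(bootstrap=False, exhaustive=True, max_depth=64)
        tree = grow_tree(P, labels, params, np.random.default_rng(0))
        preds = [predict_tree(tree, row) for row in P]
        assert preds == labels.tolist()

    def test_max_depth_bounds_recursion(self, rng):
        P = np.random.default_rng(1).random((50, 2))
        labels = np.random.default_rng(2).integers(0, 2, size=50)
        tree = grow_tree(P, labels, ForestParams(bootstrap=False, max_depth=2), rng)

        def depth(node):
            return 0 if node.is_leaf else 1 + max(depth(node.left), depth(node.right))

        assert depth(tree.root) <= 2

    def test_mismatched_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            grow_tree(np.ones((4, 2)), np.array([0, 1]), ForestParams(), rng)


def _random_tree(rng, n_features, depth=0):
    if depth >= 4 or rng.random() < 0.3:
        return TreeNode(predicted_class=int(rng.integers(2)), counts=np.array([1, 1]))
    return TreeNode(
        feature_col=int(rng.integers(n_features)),
        threshold=float(rng.random()),
        left=_random_tree(rng, n_features, depth + 1),
        right=_random_tree(rng, n_features, depth + 1),
    )


def _walk(node, x):
    """Independent recursive path-walker oracle."""
    if node.is_leaf:
        return node.predicted_class
    if x[node.feature_col] <= node.threshold:
        return _walk(node.left, x)
    return _walk(node.right, x)


class TestPredictTree:
    def test_single_leaf_tree_is_constant(self):
        tree = DecisionTree(TreeNode(predicted_class=1, counts=np.array([0, 3])), 2)
        for x in ([0.0, 0.0], [9.0, -9.0]):
            assert predict_tree(tree, x) == 1

    def test_depth_one_routing(self):
        root = TreeNode(
            feature_col=0,
            threshold=0.5,
            left=TreeNode(predicted_class=0, counts=np.array([1, 0])),
            right=TreeNode(predicted_class=1, counts=np.array([0, 1])),
        )
        tree = DecisionTree(root, 1)
        assert predict_tree(tree, [0.3]) == 0
        assert predict_tree(tree, [0.7]) == 1
        assert predict_tree(tree, [0.5]) == 0  # boundary goes left

    def test_length_mismatch_rejected(self):
        tree = DecisionTree(TreeNode(predicted_class=0, counts=np.array([1, 0])), 3)
        with pytest.raises(ValueError):
            predict_tree(tree, [0.1, 0.2])

    def test_agrees_with_recursive_walker_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n_features = int(rng.integers(1, 6))
            tree = DecisionTree(_random_tree(rng, n_features), n_features)
            for _ in range(100):
                x = rng.random(n_features)
                assert predict_tree(tree, x) == _walk(tree.root, x)


class TestPredictForest:
    def _leaf_tree(self, cls, n_features=2):
        return DecisionTree(TreeNode(predicted_class=cls, counts=np.array([1, 1])), n_features)

    def test_two_to_one_vote(self):
        from cnnforest.forest import ForestModel

        model = ForestModel([self._leaf_tree(1), self._leaf_tree(1), self._leaf_tree(0)], 2)
        cls, frac = predict_forest(model, [0.0, 0.0])
        assert cls == 1
        assert frac == pytest.approx(2 / 3)

    def test_unanimous_forest_equals_single_tree(self, rng):
        P = np.random.default_rng(2).random((20, 3))
        labels = (P[:, 1] > 0.5).astype(int)
        params = ForestParams(n_trees=1, bootstrap=False, rng_seed=5)
        model = build_forest(P, labels, params)
        [tree] = model.trees
        for row in P:
            cls, frac = predict_forest(model, row)
            assert cls == predict_tree(tree, row)
            assert frac in (0.0, 1.0)

    def test_empty_forest_rejected(self):
        from cnnforest.forest import ForestModel

        with pytest.raises(ValueError):
            predict_forest(ForestModel([], 2), [0.0, 0.0])

    def test_tie_breaks_to_negative_class(self):
        from cnnforest.forest import ForestModel

        model = ForestModel([self._leaf_tree(0), self._leaf_tree(1)], 2)
        cls, frac = predict_forest(model, [0.0, 0.0])
        assert cls == 0 and frac == 0.5

    def test_fifteen_trees_admit_no_tie(self, rng):
        P = np.random.default_rng(3).random((30, 4))
        labels = np.random.default_rng(4).integers(0, 2, size=30)
        model = build_forest(P, labels, ForestParams(n_trees=15, rng_seed=1))
        X = np.random.default_rng(5).random((50, 4))
        _, fracs = predict_forest_matrix(model, X)
        votes = fracs * 15
        assert np.allclose(votes, np.rint(votes))  # integral vote counts
        assert not np.any(np.isclose(votes, 7.5))


class TestForestBuildAndPersistence:
    def test_forest_is_deterministic_for_seed(self):
        P = np.random.default_rng(0).random((25, 3))
        labels = (P[:, 0] > 0.4).astype(int)
        a = build_forest(P, labels, ForestParams(rng_seed=7))
        b = build_forest(P, labels, ForestParams(rng_seed=7))
        X = np.random.default_rng(1).random((20, 3))
        assert np.array_equal(predict_forest_matrix(a, X)[1], predict_forest_matrix(b, X)[1])

    def test_save_load_round_trip_predictions(self, tmp_path):
        P = np.random.default_rng(0).random((25, 3))
        labels = (P[:, 0] > 0.4).astype(int)
        model = build_forest(P, labels, ForestParams(rng_seed=3))
        save_forest(model, tmp_path / "forest.json")
        back = load_forest(tmp_path / "forest.json")
        X = np.random.default_rng(9).random((30, 3))
        pa, fa = predict_forest_matrix(model, X)
        pb, fb = predict_forest_matrix(back, X)
        assert np.array_equal(pa, pb)
        assert np.array_equal(fa, fb)

    @pytest.mark.parametrize(
        "bad", [{"n_trees": 0}, {"candidates_per_node": 0}, {"max_depth": 0}]
    )
    def test_param_validation(self, bad):
        with pytest.raises(ValueError):
            ForestParams(**bad)
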