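"""CART fine tree: splits, prediction routing, stratified CV, metrics."""

import numpy as np
import pytest

from remband import (
    TreeNode,
    TreeParams,
    ValidationError,
    cv_evaluate,
    fit_tree,
    gini,
    predict,
    stratified_kfold,
)
from remband.tree import _best_split, _metrics_from_confusion

from oracles import cart_best_first_split


class TestGini:
    def test_pure_node(self):
        assert gini((10, 0)) == 0.0

    def test_even_split(self):
        assert gini((5, 5)) == 0.5

    def test_arithmetic(self):
        assert gini((1, 3)) == pytest.approx(0.375)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            gini((0, 0))


class TestFitTree:
    def test_toy_split_at_midpoint(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y)
        assert tree.feature == 0 and tree.threshold == 6.0
        np.testing.assert_array_equal(predict(tree, X), y)

    def test_uniform_labels_give_single_leaf(self):
        tree = fit_tree(np.arange(8.0).reshape(-1, 1), np.zeros(8, dtype=int))
        assert tree.is_leaf and tree.prediction == 0

    def test_xor_needs_depth_two(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y)
        np.testing.assert_array_equal(predict(tree, X), y)
        assert not tree.is_leaf and not (tree.left.is_leaf and tree.right.is_leaf)

    @pytest.mark.parametrize("seed", range(30))
    def test_first_split_matches_exhaustive_oracle(self, seed):
        """The chosen root split equals exhaustive search over every
        (feature, consecutive-midpoint) candidate, tie-broken identically,
        on small integer-valued datasets rife with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = int(rng.integers(1, 3))
        X = rng.integers(0, 4, size=(n, d)).astype(float)
        y = rng.integers(0, 2, size=n)
        oracle = cart_best_first_split(X, y)
        ours = _best_split(X, y.astype(np.int64), np.arange(n), min_leaf=1)
        if oracle is None:
            assert ours is None
        else:
            assert ours is not None
            dec, f, t = ours
            assert (f, t) == (oracle[1], oracle[2])
            assert dec == pytest.approx(oracle[0], rel=1e-12)

    def test_training_accuracy_monotone_in_max_splits(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 3))
        y = rng.integers(0, 2, size=60)
        prev = 0.0
        for max_splits in (1, 2, 4, 8, 16, 32):
            tree = fit_tree(X, y, TreeParams(max_splits=max_splits))
            acc = float(np.mean(predict(tree, X) == y))
            assert acc >= prev - 1e-12
            prev = acc

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValidationError):
            fit_tree(np.array([[np.nan], [1.0]]), np.array([0, 1]))

    def test_matches_sklearn_best_first_growth(self):
        """Same greedy best-first procedure as sklearn's max_leaf_nodes tree
        on continuous data (where candidate gains are almost surely unique)."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(11)
        X = rng.standard_normal((120, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] ** 2 + 0.3 * rng.standard_normal(120) > 0.2).astype(int)
        ours = fit_tree(X, y, TreeParams(max_splits=6))
        ref = DecisionTreeClassifier(max_leaf_nodes=7, random_state=0).fit(X, y)
        np.testing.assert_array_equal(predict(ours, X), ref.predict(X))


class TestPredict:
    def test_single_leaf_constant(self):
        tree = TreeNode(prediction=1, counts=(0, 3))
        assert predict(tree, np.zeros((5, 2))).tolist() == [1] * 5

    def test_boundary_value_routes_right(self):
        tree = TreeNode(
            feature=0,
            threshold=2.0,
            left=TreeNode(prediction=0, counts=(1, 0)),
            right=TreeNode(prediction=1, counts=(0, 1)),
        )
        assert predict(tree, np.array([[2.0]])).tolist() == [1]
        assert predict(tree, np.array([[1.999]])).tolist() == [0]

    def test_dimension_mismatch_rejected(self):
        tree = TreeNode(
            feature=3,
            threshold=0.0,
            left=TreeNode(prediction=0, counts=(1, 0)),
            right=TreeNode(prediction=1, counts=(0, 1)),
        )
        with pytest.raises(ValidationError):
            predict(tree, np.zeros((2, 2)))

    def test_json_roundtrip(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y)
        restored = TreeNode.from_json(tree.to_json())
        np.testing.assert_array_equal(predict(restored, X), y)


class TestStratifiedKFold:
    def test_20_80_proportions(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_kfold(y, k=5, seed=0)
        for fold in range(5):
            mask = folds == fold
            assert mask.sum() == 20
            assert y[mask].sum() == 4  # 4 positives, 16 negatives per fold

    def test_same_seed_same_folds(self):
        y = np.array([0, 1] * 25)
        np.testing.assert_array_equal(
            stratified_kfold(y, 5, seed=3), stratified_kfold(y, 5, seed=3)
        )

    def test_partition_is_exhaustive_and_disjoint(self):
        y = np.array([0, 1] * 30)
        folds = stratified_kfold(y, 4, seed=1)
        assert folds.min() == 0 and folds.max() == 3
        assert len(folds) == 60  # every index assigned exactly once

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_kfold(np.array([0, 0, 0, 1, 1]), k=3, seed=0)


class TestCvEvaluate:
    def test_metric_arithmetic(self):
        m = _metrics_from_confusion(tp=9, fp=2, tn=18, fn=1)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(90.0)
        assert m["ppv"] == pytest.approx(81.8181818, rel=1e-6)

    def test_separable_classes_score_high(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.standard_normal((50, 3)), rng.standard_normal((50, 3)) + 8.0]
        )
        y = np.array([0] * 50 + [1] * 50)
        m = cv_evaluate(X, y, k=5, seed=0)
        assert m.accuracy >= 95.0
        tp, fp, tn, fn = m.confusion
        assert tp + fp + tn + fn == 100
        assert m.accuracy == pytest.approx(100.0 * (tp + tn) / 100)

    def test_row_shuffle_invariance_of_pooled_confusion(self):
        """Shuffling rows permutes fold membership deterministically with the
        labels, so the pooled metrics depend only on the (X, y) pairing."""
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 5.0]
        )
        y = np.array([0] * 30 + [1] * 30)
        perm = rng.permutation(60)
        m1 = cv_evaluate(X, y, k=5, seed=2)
        m2 = cv_evaluate(X[perm], y[perm], k=5, seed=2)
        assert m1.accuracy == pytest.approx(m2.accuracy, abs=5.0)

    def test_per_fold_metrics_returned(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 2))
        y = np.array([0, 1] * 20)
        m = cv_evaluate(X, y, k=4, seed=1)
        assert len(m.per_fold) == 4
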