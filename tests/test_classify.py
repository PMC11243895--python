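"""From-scratch CART: impurity, splitting oracle, tree growth, evaluation,
train/test splitting, and the exhaustive subset search."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hrvfatigue.classify import (ConfusionCounts, TreeNode, best_split,
                                 build_tree, evaluate, exhaustive_subset_search,
                                 fit_predict_fast, gini, predict, predict_rows,
                                 train_test_split)
from hrvfatigue.features import FEATURE_NAMES


def brute_force_best_split(X, y):
    """Enumerate every (feature, midpoint) candidate and pick the weighted
    child-Gini minimum with feature-order, then lower-threshold tie-break."""
    n, k = X.shape
    parent = gini((np.sum(y == 0), np.sum(y == 1)))
    best = None
    for f in range(k):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            g = (
                len(left) * gini((np.sum(left == 0), np.sum(left == 1)))
                + len(right) * gini((np.sum(right == 0), np.sum(right == 1)))
            ) / n
            if g < parent - 1e-12 and (best is None or g < best[2] - 1e-15):
                best = (f, thr, g)
    return best


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected", [((5, 5), 0.5), ((10, 0), 0.0), ((2, 8), 0.32)]
    )
    def test_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))


class TestBestSplit:
    def test_perfectly_separated_midpoint(self):
        X = np.array([[1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 1, 1])
        name, thr, g = best_split(X, y, ["x"])
        assert name == "x"
        assert thr == pytest.approx(5.5)
        assert g == pytest.approx(0.0)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for trial in range(40):
            n = int(rng.integers(6, 21))
            X = np.round(rng.normal(size=(n, 3)), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            oracle = brute_force_best_split(X, y)
            ours = best_split(X, y, ["f0", "f1", "f2"])
            if oracle is None:
                assert ours is None
            else:
                f, thr, g = oracle
                assert ours[0] == f"f{f}"
                assert ours[1] == pytest.approx(thr)
                assert ours[2] == pytest.approx(g, abs=1e-12)

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
        y = (X[:, 1] > 0).astype(int)
        name, _, _ = best_split(X, y, ["const", "signal"])
        assert name == "signal"

    def test_no_reducing_split_returns_none(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        assert best_split(X, y, ["x"]) is None


class TestBuildTree:
    def test_separable_data_gives_depth_one_pure_tree(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        tree = build_tree(X, y, ["x"], min_samples=2)
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf
        assert np.all(predict_rows(tree, X, ["x"]) == np.array(
            ["alert", "alert", "fatigued", "fatigued"]))

    def test_min_samples_at_n_gives_majority_leaf(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        tree = build_tree(X, y, ["a", "b"], min_samples=11)
        assert tree.is_leaf
        assert tree.predicted == "fatigued"

    def test_leaf_tie_breaks_to_fatigued(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([0, 1])
        tree = build_tree(X, y, ["x"], min_samples=2)
        assert tree.is_leaf and tree.predicted == "fatigued"

    def test_matches_reference_cart_on_tie_free_fixture(self):
        from sklearn.tree import DecisionTreeClassifier

        X = np.array([
            [1.0, 5.0], [2.0, 1.0], [3.0, 4.5], [4.0, 2.0], [5.0, 3.8],
            [2.5, 6.0], [7.0, 1.5], [8.0, 6.5], [9.0, 2.5], [10.0, 7.0],
            [11.0, 3.0], [6.5, 5.5],
        ])
        y = np.array([0, 0, 1, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        tree = build_tree(X, y, ["x", "z"], min_samples=2)
        ours = (predict_rows(tree, X, ["x", "z"]) == "fatigued").astype(int)
        for random_state in range(5):
            ref = DecisionTreeClassifier(
                criterion="gini", min_samples_split=2, random_state=random_state
            ).fit(X, y)
            assert np.array_equal(ours, ref.predict(X))

    def test_fast_engine_equals_reference_builder(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(20, 120))
            X = rng.normal(size=(n, 4))
            y = ((X[:, 0] + 0.6 * X[:, 1] + rng.normal(0, 0.8, n)) > 0).astype(int)
            if y.min() == y.max():
                continue
            Xq = rng.normal(size=(50, 4))
            tree = build_tree(X, y, ["a", "b", "c", "d"], min_samples=5)
            slow = (predict_rows(tree, Xq, ["a", "b", "c", "d"]) == "fatigued")
            fast = fit_predict_fast(X, y.astype(np.int64), Xq, 5)
            assert np.array_equal(slow.astype(int), fast)

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0.2).astype(int)
        tree = build_tree(X, y, ["a", "b", "c"], min_samples=5)

        def walk(node):
            if node.is_leaf:
                return
            assert (
                node.left.class_counts[0] + node.right.class_counts[0],
                node.left.class_counts[1] + node.right.class_counts[1],
            ) == node.class_counts
            walk(node.left)
            walk(node.right)

        walk(tree)

    def test_training_accuracy_monotone_in_min_samples(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        y = ((X[:, 0] + rng.normal(0, 1.2, 60)) > 0).astype(int)
        accs = []
        for ms in (40, 20, 10, 5, 2):
            tree = build_tree(X, y, ["a", "b", "c"], min_samples=ms)
            pred = (predict_rows(tree, X, ["a", "b", "c"]) == "fatigued").astype(int)
            accs.append(np.mean(pred == y))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))


class TestPredict:
    def test_single_leaf_constant(self):
        leaf = TreeNode(gini=0.0, class_counts=(0, 4), predicted="fatigued")
        assert predict(leaf, {"MRR": 1.0}) == "fatigued"

    def test_missing_feature_named(self):
        X = np.array([[1.0], [9.0]])
        tree = build_tree(X, [0, 1], ["MRR"], min_samples=2)
        with pytest.raises(KeyError, match="MRR"):
            predict(tree, {"DRR": 5.0})

    def test_hand_traced_routing(self):
        # root: x <= 5 -> left leaf alert; else z <= 2 -> fatigued / alert
        inner = TreeNode(gini=0.4, class_counts=(2, 3), predicted="fatigued",
                         split_feature="z", threshold=2.0,
                         left=TreeNode(0.0, (0, 3), "fatigued"),
                         right=TreeNode(0.0, (2, 0), "alert"))
        root = TreeNode(gini=0.5, class_counts=(5, 3), predicted="alert",
                        split_feature="x", threshold=5.0,
                        left=TreeNode(0.0, (3, 0), "alert"), right=inner)
        probes = [
            ({"x": 1.0, "z": 0.0}, "alert"),
            ({"x": 5.0, "z": 9.0}, "alert"),    # boundary goes left
            ({"x": 6.0, "z": 1.5}, "fatigued"),
            ({"x": 6.0, "z": 2.0}, "fatigued"),
            ({"x": 9.0, "z": 2.1}, "alert"),
        ]
        for x, expected in probes:
            assert predict(root, x) == expected


def _label_frame(n_alert, n_fatigued, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    labels = ["alert"] * n_alert + ["fatigued"] * n_fatigued
    df = pd.DataFrame(
        rng.normal(size=(len(labels), n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    df["label"] = labels
    df["subject_id"] = [f"s{i % 6}" for i in range(len(labels))]
    return df


class TestTrainTestSplit:
    def test_eighty_twenty(self):
        df = _label_frame(40, 60)
        train, test = train_test_split(df, 0.2, seed=1)
        assert len(train) == 80 and len(test) == 20

    def test_stratified_per_label_rounding(self):
        df = _label_frame(60, 140)
        train, test = train_test_split(df, 0.2, seed=2, stratify=True)
        assert (test["label"] == "alert").sum() == 12
        assert (test["label"] == "fatigued").sum() == 28

    def test_determinism_and_seed_sensitivity(self):
        df = _label_frame(30, 30)
        t1, _ = train_test_split(df, 0.2, seed=3)
        t2, _ = train_test_split(df, 0.2, seed=3)
        t3, _ = train_test_split(df, 0.2, seed=4)
        assert t1.index.equals(t2.index)
        assert not t1.index.equals(t3.index)

    def test_subject_wise_split_keeps_subjects_together(self):
        df = _label_frame(30, 30)
        train, test = train_test_split(df, 0.3, seed=5, subject_wise=True)
        assert set(train["subject_id"]).isdisjoint(set(test["subject_id"]))

    def test_tiny_stratum_rejected(self):
        df = _label_frame(1, 20)
        with pytest.raises(ValueError, match="alert"):
            train_test_split(df, 0.2, seed=0, stratify=True)


class TestEvaluate:
    def test_formula_arithmetic(self):
        cm = ConfusionCounts(tp=9, tn=8, fp=1, fn=2)
        assert cm.sen == pytest.approx(81.8, abs=0.05)
        assert cm.spe == pytest.approx(88.9, abs=0.05)
        assert cm.ppv == pytest.approx(90.0, abs=0.05)
        assert cm.acc == pytest.approx(85.0, abs=0.05)

    def test_all_fatigued_predictor(self):
        leaf = TreeNode(gini=0.0, class_counts=(0, 1), predicted="fatigued")
        X = np.zeros((40, 1))
        y = ["alert"] * 10 + ["fatigued"] * 30
        cm = evaluate(leaf, X, y, ["f0"])
        assert (cm.sen, cm.spe, cm.ppv, cm.acc) == (100.0, 0.0, 75.0, 75.0)
        assert cm.tp + cm.tn + cm.fp + cm.fn == 40

    def test_perfect_classifier(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = ["alert", "alert", "fatigued", "fatigued"]
        tree = build_tree(X, [0, 0, 1, 1], ["x"], min_samples=2)
        cm = evaluate(tree, X, y, ["x"])
        assert (cm.sen, cm.spe, cm.ppv, cm.acc) == (100.0, 100.0, 100.0, 100.0)

    def test_undefined_metric_is_nan(self):
        cm = ConfusionCounts(tp=0, tn=5, fp=0, fn=0)
        assert math.isnan(cm.sen)
        assert math.isnan(cm.ppv)


class TestSubsetSearch:
    def test_subset_count_k1(self):
        df = _label_frame(15, 25, seed=6, n_features=20)
        df.columns = list(FEATURE_NAMES) + ["label", "subject_id"]
        results = exhaustive_subset_search(df, k=1, seed=0)
        assert len(results) == 20

    def test_ranking_and_tie_break_order(self):
        df = _label_frame(20, 30, seed=7, n_features=5)
        results = exhaustive_subset_search(
            df, k=2, seed=1, feature_names=[f"f{i}" for i in range(5)]
        )
        assert len(results) == math.comb(5, 2)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        accs = [r.metrics.acc for r in results]
        assert accs == sorted(accs, reverse=True)
        assert results[0].tree is not None and results[1].tree is None

    def test_shared_split_makes_counts_consistent(self):
        df = _label_frame(24, 36, seed=8, n_features=4)
        results = exhaustive_subset_search(
            df, k=2, seed=2, feature_names=["f0", "f1", "f2", "f3"]
        )
        totals = {
            r.metrics.tp + r.metrics.tn + r.metrics.fp + r.metrics.fn
            for r in results
        }
        assert len(totals) == 1  # same held-out rows for every subset
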