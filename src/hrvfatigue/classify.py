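"""From-scratch CART fatigue classifier with exhaustive feature-subset search.

Binary classification trees grown by greedy Gini-impurity minimisation:
candidate thresholds are midpoints between consecutive distinct sorted
feature values; a node becomes a leaf when pure, when it holds fewer than
``min_samples`` rows, or when no split strictly reduces impurity.  Leaves
predict their majority class, ties going to 'fatigued' (the majority class
of the study design).  No pruning is applied.  All tie-breaking is
deterministic: candidate features are scanned in the canonical feature
order and thresholds in ascending order, and only a strictly better
weighted child Gini displaces the incumbent.

Two numerically identical engines are provided: a readable recursive
builder producing :class:`TreeNode` structures, and a flat-array engine
compiled with numba that makes the exhaustive search over all 190 / 1140 /
4845 two-/three-/four-feature subsets fast.  Model quality is measured on a
held-out 20% test split (stratified by label) shared across all subsets of
a search, with sensitivity / specificity / PPV / accuracy computed from the
confusion counts, 'fatigued' being the positive class.

Segments from overlapping windows are correlated, so a segment-level split
leaks information between train and test; this mirrors the study design.
A subject-wise split mode is available for leakage-free evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit

from .features import FEATURE_NAMES

__all__ = [
    "TreeNode",
    "ConfusionCounts",
    "SubsetSearchResult",
    "gini",
    "best_split",
    "build_tree",
    "predict",
    "predict_rows",
    "train_test_split",
    "evaluate",
    "exhaustive_subset_search",
    "format_tree",
]

LABEL_TO_INT = {"alert": 0, "fatigued": 1}
INT_TO_LABEL = {0: "alert", 1: "fatigued"}

#: margin below the parent impurity a split must reach to count as a
#: strict reduction (guards against float noise creating spurious splits)
_IMPROVEMENT_EPS = 1e-12


@dataclass
class TreeNode:
    """One node of a binary CART; a leaf has no children."""

    gini: float
    class_counts: tuple[int, int]  # (n_alert, n_fatigued)
    predicted: str
    split_feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with 'fatigued' as the positive class; metrics in %."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sen(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def spe(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def acc(self) -> float:
        d = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / d if d else float("nan")


@dataclass(frozen=True)
class SubsetSearchResult:
    feature_subset: tuple[str, ...]
    metrics: ConfusionCounts
    rank: int
    tree: TreeNode | None = None


# ---------------------------------------------------------------------------
# impurity and splitting
# ---------------------------------------------------------------------------

def gini(class_counts) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty node has no impurity")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _as_xy(X, y, feature_names):
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    yi = np.asarray(
        [LABEL_TO_INT[v] if isinstance(v, str) else int(v) for v in y],
        dtype=np.int64,
    )
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    return X, yi, tuple(feature_names)


def _scan_feature(values: np.ndarray, labels: np.ndarray, c1_total: int):
    """Best (threshold, weighted child gini) for one feature, or None."""
    m = values.size
    order = np.argsort(values, kind="stable")
    v = values[order]
    lab = labels[order]
    best = None
    c1cum = 0
    for i in range(m - 1):
        c1cum += lab[i]
        if v[i + 1] > v[i]:
            nl = i + 1
            nr = m - nl
            l1 = c1cum
            l0 = nl - l1
            r1 = c1_total - l1
            r0 = nr - r1
            g = (
                nl * (1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2)
                + nr * (1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2)
            ) / m
            if best is None or g < best[1]:
                best = (0.5 * (v[i] + v[i + 1]), g)
    return best


def best_split(X, y, feature_names=None):
    """Exhaustively scan (feature, midpoint-threshold) pairs.

    Returns ``(feature_name, threshold, weighted_child_gini)`` minimising the
    sample-weighted child Gini, or ``None`` when no split strictly reduces
    the parent impurity (e.g. all-constant features).  Ties are broken by
    feature order, then by the lower threshold (ascending scan keeps the
    first strict minimum).
    """
    X, yi, names = _as_xy(X, y, feature_names)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to split")
    c1 = int(yi.sum())
    c0 = yi.size - c1
    if c0 == 0 or c1 == 0:
        return None
    parent = gini((c0, c1))
    best = None  # (gini, feature index, threshold)
    for f in range(X.shape[1]):
        cand = _scan_feature(X[:, f], yi, c1)
        if cand is None:
            continue
        thr, g = cand
        if g < parent - _IMPROVEMENT_EPS and (best is None or g < best[0]):
            best = (g, f, thr)
    if best is None:
        return None
    g, f, thr = best
    return names[f], float(thr), float(g)


def build_tree(X, y, feature_names=None, min_samples: int = 5) -> TreeNode:
    """Grow a CART by recursive binary splitting.

    A node becomes a leaf when pure, when it holds fewer than
    ``min_samples`` rows, or when no impurity-reducing split exists.
    """
    X, yi, names = _as_xy(X, y, feature_names)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")

    def grow(rows: np.ndarray) -> TreeNode:
        sub_y = yi[rows]
        c1 = int(sub_y.sum())
        c0 = sub_y.size - c1
        node = TreeNode(
            gini=gini((c0, c1)),
            class_counts=(c0, c1),
            predicted=INT_TO_LABEL[1 if c1 >= c0 else 0],
        )
        if c0 == 0 or c1 == 0 or sub_y.size < min_samples:
            return node
        split = best_split(X[rows], sub_y, names)
        if split is None:
            return node
        fname, thr, _ = split
        f = names.index(fname)
        go_left = X[rows, f] <= thr
        node.split_feature = fname
        node.threshold = thr
        node.left = grow(rows[go_left])
        node.right = grow(rows[~go_left])
        return node

    return grow(np.arange(X.shape[0]))


def predict(tree: TreeNode, x) -> str:
    """Route one sample down the tree; ``x`` is a mapping (or FeatureVector)
    of feature name -> value.  Left on value <= threshold."""
    if hasattr(x, "to_dict"):
        x = x.to_dict()
    node = tree
    while not node.is_leaf:
        if node.split_feature not in x:
            raise KeyError(f"sample is missing feature {node.split_feature!r}")
        value = x[node.split_feature]
        node = node.left if value <= node.threshold else node.right
    return node.predicted


def predict_rows(tree: TreeNode, X, feature_names) -> np.ndarray:
    """Vectorised routing of an array of samples; returns label strings."""
    X = np.asarray(X, dtype=float)
    names = list(feature_names)
    out = []
    for row in X:
        out.append(predict(tree, dict(zip(names, row))))
    return np.asarray(out)


def format_tree(tree: TreeNode, indent: str = "") -> str:
    """Indented text dump of the tree."""
    c0, c1 = tree.class_counts
    head = f"{indent}gini={tree.gini:.4f} counts=(alert={c0}, fatigued={c1})"
    if tree.is_leaf:
        return f"{head} -> predict {tree.predicted}\n"
    out = f"{head} split {tree.split_feature} <= {tree.threshold:.6g}\n"
    out += format_tree(tree.left, indent + "  ")
    out += format_tree(tree.right, indent + "  ")
    return out


# ---------------------------------------------------------------------------
# fast flat-array engine (numerically identical to build_tree/predict)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grow_arrays(X, y, min_samples):  # pragma: no cover - exercised via wrapper
    n, k = X.shape
    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    pred = np.zeros(max_nodes, np.int64)
    idx = np.arange(n)
    stack = np.empty((max_nodes, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        node = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        m = e - s
        c1 = 0
        for i in range(s, e):
            c1 += y[idx[i]]
        c0 = m - c1
        pred[node] = 1 if c1 >= c0 else 0
        if c0 == 0 or c1 == 0 or m < min_samples:
            continue
        parent = 1.0 - (c0 / m) ** 2 - (c1 / m) ** 2
        best_g = parent - 1e-12
        best_f = -1
        best_t = 0.0
        vals = np.empty(m)
        labs = np.empty(m, np.int64)
        for f in range(k):
            for i in range(m):
                vals[i] = X[idx[s + i], f]
                labs[i] = y[idx[s + i]]
            order = np.argsort(vals)
            c1cum = 0
            for i in range(m - 1):
                c1cum += labs[order[i]]
                v_cur = vals[order[i]]
                v_next = vals[order[i + 1]]
                if v_next > v_cur:
                    nl = i + 1
                    nr = m - nl
                    l1 = c1cum
                    l0 = nl - l1
                    r1 = c1 - l1
                    r0 = nr - r1
                    g = (
                        nl * (1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2)
                        + nr * (1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2)
                    ) / m
                    if g < best_g:
                        best_g = g
                        best_f = f
                        best_t = 0.5 * (v_cur + v_next)
        if best_f < 0:
            continue
        buf = np.empty(m, np.int64)
        nl = 0
        for i in range(s, e):
            if X[idx[i], best_f] <= best_t:
                buf[nl] = idx[i]
                nl += 1
        pos = nl
        for i in range(s, e):
            if X[idx[i], best_f] > best_t:
                buf[pos] = idx[i]
                pos += 1
        for i in range(m):
            idx[s + i] = buf[i]
        feat[node] = best_f
        thr[node] = best_t
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        stack[top, 0] = lid
        stack[top, 1] = s
        stack[top, 2] = s + nl
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = s + nl
        stack[top, 2] = e
        top += 1
    return feat, thr, left, right, pred


@njit(cache=True)
def _predict_arrays(X, feat, thr, left, right, pred):  # pragma: no cover
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while feat[node] >= 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = pred[node]
    return out


def fit_predict_fast(X_train, y_train, X_test, min_samples: int = 5) -> np.ndarray:
    """Fit the flat-array CART and predict test labels (ints 0/1)."""
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    X_test = np.ascontiguousarray(X_test, dtype=np.float64)
    y_train = np.ascontiguousarray(y_train, dtype=np.int64)
    arrays = _grow_arrays(X_train, y_train, min_samples)
    return _predict_arrays(X_test, *arrays)


# ---------------------------------------------------------------------------
# split, evaluation, subset search
# ---------------------------------------------------------------------------

def train_test_split(
    df: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
    label_col: str = "label",
    subject_wise: bool = False,
    subject_col: str = "subject_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible shuffled train/test split.

    With ``stratify`` each label contributes ``round(n_label *
    test_fraction)`` rows to the test set.  With ``subject_wise`` whole
    subjects are assigned to the test set until the test fraction is
    reached, avoiding leakage between overlapping windows of one subject.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if subject_wise:
        subjects = df[subject_col].unique()
        rng.shuffle(subjects)
        target = test_fraction * len(df)
        test_subj, n_acc = [], 0
        for s in subjects:
            if n_acc >= target:
                break
            test_subj.append(s)
            n_acc += int((df[subject_col] == s).sum())
        mask = df[subject_col].isin(test_subj)
        return df[~mask].copy(), df[mask].copy()
    if stratify:
        test_idx = []
        for label, grp in df.groupby(label_col, sort=True):
            if len(grp) < 2:
                raise ValueError(
                    f"label {label!r} has {len(grp)} row(s); cannot stratify"
                )
            n_test = int(round(len(grp) * test_fraction))
            n_test = min(max(n_test, 1), len(grp) - 1)
            perm = rng.permutation(grp.index.to_numpy())
            test_idx.extend(perm[:n_test])
        mask = df.index.isin(test_idx)
        return df[~mask].copy(), df[mask].copy()
    perm = rng.permutation(df.index.to_numpy())
    n_test = int(round(len(df) * test_fraction))
    test_set = set(perm[:n_test])
    mask = df.index.isin(test_set)
    return df[~mask].copy(), df[mask].copy()


def evaluate(tree: TreeNode, X_test, y_test, feature_names) -> ConfusionCounts:
    """Confusion counts of a tree on held-out rows ('fatigued' positive)."""
    y_true = np.asarray(
        [LABEL_TO_INT[v] if isinstance(v, str) else int(v) for v in y_test],
        dtype=np.int64,
    )
    if y_true.size == 0:
        raise ValueError("test set is empty")
    y_pred = np.asarray(
        [LABEL_TO_INT[p] for p in predict_rows(tree, X_test, feature_names)],
        dtype=np.int64,
    )
    return _confusion(y_true, y_pred)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def exhaustive_subset_search(
    df: pd.DataFrame,
    k: int,
    min_samples: int = 5,
    seed: int = 0,
    feature_names=FEATURE_NAMES,
    label_col: str = "label",
    test_fraction: float = 0.2,
    subject_wise: bool = False,
    top_trees: int = 1,
) -> list[SubsetSearchResult]:
    """Evaluate a CART on every k-feature subset and rank by test accuracy.

    One train/test split (derived from ``seed``) is shared across all
    subsets so accuracies are directly comparable.  Ranking is by test ACC,
    ties broken by SEN, then by subset position in the canonical feature
    order.  ``TreeNode`` structures are attached to the ``top_trees``
    best-ranked results.
    """
    if not 1 <= k <= len(feature_names):
        raise ValueError(f"k must lie in 1..{len(feature_names)}")
    train, test = train_test_split(
        df, test_fraction=test_fraction, seed=seed, stratify=not subject_wise,
        label_col=label_col, subject_wise=subject_wise,
    )
    names = list(feature_names)
    Xtr = np.ascontiguousarray(train[names].to_numpy(dtype=np.float64))
    Xte = np.ascontiguousarray(test[names].to_numpy(dtype=np.float64))
    ytr = np.ascontiguousarray(
        train[label_col].map(LABEL_TO_INT).to_numpy(dtype=np.int64)
    )
    yte = test[label_col].map(LABEL_TO_INT).to_numpy(dtype=np.int64)

    scored = []
    for pos, cols in enumerate(combinations(range(len(names)), k)):
        cidx = np.asarray(cols, dtype=np.int64)
        y_pred = fit_predict_fast(Xtr[:, cidx], ytr, Xte[:, cidx], min_samples)
        cm = _confusion(yte, y_pred)
        scored.append((cm.acc, cm.sen, pos, cols, cm))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))

    results = []
    for rank, (_, _, _, cols, cm) in enumerate(scored, start=1):
        subset = tuple(names[c] for c in cols)
        tree = None
        if rank <= top_trees:
            cidx = np.asarray(cols, dtype=np.int64)
            tree = build_tree(Xtr[:, cidx], ytr, subset, min_samples=min_samples)
        results.append(
            SubsetSearchResult(feature_subset=subset, metrics=cm, rank=rank, tree=tree)
        )
    return results
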