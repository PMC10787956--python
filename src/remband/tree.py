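"""CART binary classifier with stratified k-fold cross-validation.

A from-scratch "fine tree": greedy best-first growth under the Gini
criterion with midpoint thresholds and a cap of 100 splits (the preset many
commercial toolboxes call a fine tree), minimum leaf size 1. At each step
the frontier node whose best (feature, threshold) candidate yields the
largest weighted impurity decrease is split; ties break on the lowest
feature index, then the lowest threshold. Routing convention: a value
strictly below the threshold goes left; a value equal to the threshold goes
right.

Cross-validation is stratified by class with a seeded shuffle. The four
reported metrics use bruxism as the positive class and are computed from the
confusion matrix pooled over folds (micro-averaging); per-fold metrics are
also returned.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError


@dataclass
class TreeNode:
    """Internal split or leaf. Leaves carry class counts of training rows."""

    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    prediction: Optional[int] = None
    counts: Optional[Tuple[int, int]] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "prediction": int(self.prediction), "counts": list(self.counts)}
        return {
            "leaf": False,
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(prediction=d["prediction"], counts=tuple(d["counts"]))
        return cls(
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TreeNode":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TreeParams:
    """Fine-tree preset: Gini criterion, up to 100 splits, leaves of >= 1 row."""

    max_splits: int = 100
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.max_splits < 1 or self.min_leaf < 1:
            raise ValidationError("max_splits and min_leaf must be >= 1")


@dataclass
class CVMetrics:
    """Pooled k-fold metrics, percentages; bruxism (label 1) is positive."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    confusion: Tuple[int, int, int, int]  # (TP, FP, TN, FN)
    k: int
    seed: int
    per_fold: List[Dict[str, float]] = field(default_factory=list)


def gini(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any() or counts.sum() == 0:
        raise ValidationError("class counts must be non-negative and not all zero")
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def _best_split(
    X: np.ndarray, y: np.ndarray, rows: np.ndarray, min_leaf: int
) -> Optional[Tuple[float, int, float]]:
    """Best (impurity decrease, feature, midpoint threshold) for one node.

    The decrease is the unnormalized weighted Gini gain
    ``n*G(node) - n_l*G(left) - n_r*G(right)``. Candidates are midpoints
    between consecutive distinct sorted values; ties resolve to the lowest
    feature index, then the lowest threshold.
    """
    ysub = y[rows]
    n = len(rows)
    n_pos = int(ysub.sum())
    if n_pos == 0 or n_pos == n:
        return None
    parent = n * gini((n - n_pos, n_pos))
    best: Optional[Tuple[float, int, float]] = None
    for f in range(X.shape[1]):
        vals = X[rows, f]
        order = np.argsort(vals, kind="mergesort")
        v = vals[order]
        pos = ysub[order]
        cum_pos = np.cumsum(pos)
        distinct = np.nonzero(np.diff(v) > 0)[0]  # split after index i
        for i in distinct:
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            lp = int(cum_pos[i])
            rp = n_pos - lp
            decrease = (
                parent
                - nl * gini((nl - lp, lp))
                - nr * gini((nr - rp, rp))
            )
            # zero-gain splits of impure nodes are admitted (classic CART;
            # needed e.g. for XOR layouts where no single split helps)
            threshold = 0.5 * (v[i] + v[i + 1])
            cand = (decrease, f, threshold)
            if (
                best is None
                or decrease > best[0] + 1e-12
                or (
                    abs(decrease - best[0]) <= 1e-12
                    and (f, threshold) < (best[1], best[2])
                )
            ):
                best = cand
    return best


def _leaf(y: np.ndarray, rows: np.ndarray) -> TreeNode:
    n_pos = int(y[rows].sum())
    n_neg = len(rows) - n_pos
    # majority class; ties go to the smaller label
    pred = 1 if n_pos > n_neg else 0
    return TreeNode(prediction=pred, counts=(n_neg, n_pos))


def fit_tree(X: np.ndarray, y: np.ndarray, params: TreeParams = TreeParams()) -> TreeNode:
    """Grow a CART tree best-first until ``max_splits`` or purity.

    Deterministic given the input order; at each step the frontier node with
    the largest weighted Gini decrease is expanded. Impure nodes admit
    zero-gain splits (the best candidate by the tie-break order), so
    non-linearly-separable layouts such as XOR are still resolved by depth.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be 2-D with one label per row")
    if len(y) < 1:
        raise ValidationError("need at least one training row")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    y = y.astype(np.int64)

    all_rows = np.arange(len(y))
    root = _leaf(y, all_rows)
    counter = 0  # FIFO tie-break for equal gains across frontier nodes
    heap: List[Tuple[float, int, TreeNode, np.ndarray, Tuple[float, int, float]]] = []

    def push(node: TreeNode, rows: np.ndarray) -> None:
        nonlocal counter
        cand = _best_split(X, y, rows, params.min_leaf)
        if cand is not None:
            heapq.heappush(heap, (-cand[0], counter, node, rows, cand))
            counter += 1

    push(root, all_rows)
    for _ in range(params.max_splits):
        if not heap:
            break
        _, _, node, rows, (decrease, f, threshold) = heapq.heappop(heap)
        mask = X[rows, f] < threshold
        left_rows, right_rows = rows[mask], rows[~mask]
        node.feature = f
        node.threshold = threshold
        node.prediction = None
        node.counts = None
        node.left = _leaf(y, left_rows)
        node.right = _leaf(y, right_rows)
        push(node.left, left_rows)
        push(node.right, right_rows)
    return root


def predict(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Route rows through the tree; value < threshold goes left, equal goes right."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    max_feature = _max_feature(tree)
    if max_feature >= X.shape[1]:
        raise ValidationError(
            f"tree uses feature index {max_feature} but X has {X.shape[1]} columns"
        )
    out = np.empty(len(X), dtype=np.int64)
    for i, row in enumerate(X):
        node = tree
        while not node.is_leaf:
            node = node.left if row[node.feature] < node.threshold else node.right
        out[i] = node.prediction
    return out


def _max_feature(tree: TreeNode) -> int:
    if tree.is_leaf:
        return -1
    return max(tree.feature, _max_feature(tree.left), _max_feature(tree.right))


def stratified_kfold(y: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Fold index per row: seeded, class-stratified, exhaustive partition."""
    y = np.asarray(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if (counts < k).any():
        raise ValidationError(
            f"every class needs >= k={k} members, got counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = fold
    return folds


def _metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> Dict[str, float]:
    total = tp + fp + tn + fn
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
        "accuracy": 100.0 * (tp + tn) / total if total else np.nan,
        "ppv": 100.0 * tp / (tp + fp) if tp + fp else np.nan,
    }


def cv_evaluate(
    X: np.ndarray,
    y: Sequence[int],
    params: TreeParams = TreeParams(),
    k: int = 5,
    seed: int = 0,
) -> CVMetrics:
    """Stratified k-fold CV of the fine tree; metrics pooled over folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    folds = stratified_kfold(y, k, seed)
    tp = fp = tn = fn = 0
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValidationError(f"fold {fold}: training data has a single class")
        tree = fit_tree(X[train], y[train], params)
        pred = predict(tree, X[test])
        truth = y[test]
        f_tp = int(np.sum((pred == 1) & (truth == 1)))
        f_fp = int(np.sum((pred == 1) & (truth == 0)))
        f_tn = int(np.sum((pred == 0) & (truth == 0)))
        f_fn = int(np.sum((pred == 0) & (truth == 1)))
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
        per_fold.append({"fold": fold, **_metrics_from_confusion(f_tp, f_fp, f_tn, f_fn)})
    pooled = _metrics_from_confusion(tp, fp, tn, fn)
    return CVMetrics(
        sensitivity=pooled["sensitivity"],
        specificity=pooled["specificity"],
        accuracy=pooled["accuracy"],
        ppv=pooled["ppv"],
        confusion=(tp, fp, tn, fn),
        k=k,
        seed=seed,
        per_fold=per_fold,
    )
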