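"""CART binary classification trees with cost-complexity pruning.

Trees are grown greedily on the learning split: at every node the
axis-aligned threshold split with the largest Gini-impurity decrease is
taken (no minimum node size), stopping only at pure nodes or when no split
improves impurity.  Ties are broken deterministically — lowest feature
index, then lowest threshold — and thresholds sit at midpoints of
consecutive sorted values.  A leaf with a class tie predicts "disease",
favouring sensitivity in a screening setting.

Pruning follows the classic weakest-link cost-complexity procedure: the
nested subtree sequence T0 ⊃ T1 ⊃ … ⊃ {root} is computed, the
misclassification cost of each subtree is estimated either by 10-fold
cross-validation on the learning split or on a held-out validation split,
and the smallest subtree whose cost is within one standard error of the
minimum is selected (the 1-SE rule).

Labels are binary with 1 = disease (positive) and 0 = healthy.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np


class DegenerateDataError(ValueError):
    """The data cannot support the requested operation."""


# ---------------------------------------------------------------------------
# dataset


@dataclass
class Dataset:
    """Feature matrix with binary labels and learn/valid/test split tags."""

    X: np.ndarray
    y: np.ndarray
    split: np.ndarray  # entries in {"learn", "valid", "test"}
    feature_names: tuple | None = None

    def _part(self, tag):
        m = self.split == tag
        return self.X[m], self.y[m]

    @property
    def learning(self):
        return self._part("learn")

    @property
    def validation(self):
        return self._part("valid")

    @property
    def test(self):
        return self._part("test")


def split_equal_thirds(X, y, seed: int, feature_names=None) -> Dataset:
    """Random stratified partition into near-equal learn/valid/test groups.

    Within each class the samples are shuffled and dealt into three chunks
    whose sizes differ by at most one; the assignment is deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < 6:
        raise DegenerateDataError("need at least 6 samples for a 3-way split")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateDataError("both classes must be present")
    rng = np.random.default_rng(seed)
    tags = np.empty(len(y), dtype=object)
    names = ("learn", "valid", "test")
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        # rotate which group receives the remainder so class remainders
        # do not all land on the same group
        order = np.roll(np.arange(3), -ci)
        for g, chunk in zip(order, np.array_split(idx, 3)):
            tags[chunk] = names[g]
    return Dataset(X, y, tags.astype("U5"), feature_names)


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    counts: np.ndarray  # class counts (healthy, disease) of learning samples
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        # tie -> disease
        return 1 if self.counts[1] >= self.counts[0] else 0


@dataclass
class TreeModel:
    """A fitted CART tree."""

    root: TreeNode
    n_features: int
    pruned: bool = False

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self._walk() if n.is_leaf)

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self._walk())

    def _walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.left)
                stack.append(node.right)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def to_dict(self) -> dict:
        """Nested-dict export (feature index, threshold, children, leaf class)."""

        def conv(node):
            if node.is_leaf:
                return {"leaf": int(node.prediction), "n": int(node.counts.sum())}
            return {
                "feature": int(node.feature),
                "threshold": float(node.threshold),
                "left": conv(node.left),
                "right": conv(node.right),
            }

        return conv(self.root)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# growing


def _gini(counts) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _best_split(X, y):
    """Best Gini split of one node; None if no split reduces impurity."""
    n, k = X.shape
    total1 = y.sum()
    counts = np.array([n - total1, total1], dtype=float)
    parent = _gini(counts)
    if parent == 0.0:
        return None
    best = None  # (decrease, feature, threshold)
    positions = np.arange(1, n, dtype=float)
    for j in range(k):
        xs = X[:, j]
        order = np.argsort(xs, kind="stable")
        xv = xs[order]
        yv = y[order]
        cut = xv[:-1] < xv[1:]
        if not cut.any():
            continue
        cum1 = np.cumsum(yv)[:-1]
        nl = positions[cut]
        p1l = cum1[cut]
        p0l = nl - p1l
        nr = n - nl
        p1r = total1 - p1l
        p0r = nr - p1r
        gl = 1.0 - (p1l**2 + p0l**2) / nl**2
        gr = 1.0 - (p1r**2 + p0r**2) / nr**2
        decrease = parent - (nl * gl + nr * gr) / n
        i = int(np.argmax(decrease))  # first max = lowest threshold
        if decrease[i] > 1e-12 and (best is None or decrease[i] > best[0] + 1e-12):
            thr = 0.5 * (xv[:-1][cut][i] + xv[1:][cut][i])
            best = (float(decrease[i]), j, float(thr))
    return best


def _grow(X, y) -> TreeNode:
    total1 = y.sum()
    node = TreeNode(np.array([len(y) - total1, total1], dtype=float))
    split = _best_split(X, y)
    if split is None:
        return node
    _, j, thr = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], y[mask])
    node.right = _grow(X[~mask], y[~mask])
    return node


def fit_cart(X, y) -> TreeModel:
    """Grow a full CART tree on the learning data.

    Growth is unrestricted (no minimum node size); recursion stops at pure
    nodes or when no split decreases Gini impurity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("learning split must contain both classes")
    return TreeModel(_grow(X, y), X.shape[1])


# ---------------------------------------------------------------------------
# cost-complexity pruning


def _leaf_errors(node, out):
    """Sum of misclassified learning samples over the subtree's leaves."""
    if node.is_leaf:
        err = node.counts.sum() - node.counts.max()
        out[id(node)] = (err, 1)
        return err, 1
    el, ll = _leaf_errors(node.left, out)
    er, lr = _leaf_errors(node.right, out)
    out[id(node)] = (el + er, ll + lr)
    return el + er, ll + lr


def cost_complexity_path(model: TreeModel):
    """Weakest-link pruning sequence of nested subtrees.

    Returns ``(alphas, subtrees)`` with ``alphas[0] = 0`` for the full tree
    and monotonically nondecreasing complexity parameters; the last subtree
    is the root stump.
    """
    n_total = model.root.counts.sum()
    current = copy.deepcopy(model)
    alphas = [0.0]
    subtrees = [copy.deepcopy(current)]
    while not current.root.is_leaf:
        info: dict[int, tuple] = {}
        _leaf_errors(current.root, info)
        gmin = np.inf
        for node in current._walk():
            if node.is_leaf:
                continue
            sub_err, sub_leaves = info[id(node)]
            own_err = node.counts.sum() - node.counts.max()
            g = (own_err - sub_err) / (n_total * (sub_leaves - 1))
            gmin = min(gmin, g)
        for node in current._walk():
            if node.is_leaf:
                continue
            sub_err, sub_leaves = info[id(node)]
            own_err = node.counts.sum() - node.counts.max()
            g = (own_err - sub_err) / (n_total * (sub_leaves - 1))
            if g <= gmin + 1e-12:
                node.feature = None
                node.threshold = None
                node.left = None
                node.right = None
        alphas.append(float(max(gmin, alphas[-1])))
        subtrees.append(copy.deepcopy(current))
    return alphas, subtrees


def _stratified_folds(y, folds, rng):
    """Fold assignment, classes spread as evenly as possible."""
    assign = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def _subtree_for_alpha(alphas, subtrees, alpha):
    """Subtree whose alpha interval contains ``alpha``."""
    k = int(np.searchsorted(np.asarray(alphas), alpha, side="right")) - 1
    return subtrees[max(k, 0)]


def prune_one_se(
    tree: TreeModel,
    X,
    y,
    *,
    method: str = "cv",
    folds: int = 10,
    seed: int = 0,
    validation=None,
) -> TreeModel:
    """Prune by the 1-SE rule over the cost-complexity sequence.

    ``method="cv"`` estimates the misclassification cost of each candidate
    complexity by ``folds``-fold stratified cross-validation on the learning
    data ``(X, y)``; ``method="validation"`` evaluates each subtree on the
    held-out split passed as ``validation=(Xv, yv)``.  In both cases the
    smallest subtree whose cost is at most one standard error above the
    minimum is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    alphas, subtrees = cost_complexity_path(tree)
    if len(subtrees) == 1:
        pruned = copy.deepcopy(tree)
        pruned.pruned = True
        return pruned

    if method == "validation":
        if validation is None:
            raise ValueError("method='validation' requires validation=(Xv, yv)")
        Xv = np.atleast_2d(np.asarray(validation[0], dtype=float))
        yv = np.asarray(validation[1]).astype(int)
        n_eval = len(yv)
        rates = np.array([(sub.predict(Xv) != yv).mean() for sub in subtrees])
    elif method == "cv":
        # representative alpha for each step of the main sequence
        a = np.asarray(alphas)
        beta = np.empty(len(a))
        beta[:-1] = np.sqrt(a[:-1] * a[1:])
        beta[-1] = np.inf
        n_eval = len(y)
        folds = int(min(folds, np.bincount(y).min()))
        if folds < 2:
            raise DegenerateDataError("cross-validation needs >= 2 samples per class")
        rng = np.random.default_rng(seed)
        assign = _stratified_folds(y, folds, rng)
        errors = np.zeros(len(beta))
        for f in range(folds):
            train = assign != f
            fold_model = fit_cart(X[train], y[train])
            fa, fs = cost_complexity_path(fold_model)
            held_X, held_y = X[~train], y[~train]
            for k, b in enumerate(beta):
                sub = _subtree_for_alpha(fa, fs, b)
                errors[k] += (sub.predict(held_X) != held_y).sum()
        rates = errors / n_eval
    else:
        raise ValueError(f"unknown pruning method {method!r}")

    rmin = rates.min()
    se = np.sqrt(rmin * (1.0 - rmin) / n_eval)
    # subtrees are ordered by decreasing size; take the smallest within 1 SE
    k = int(np.max(np.flatnonzero(rates <= rmin + se)))
    pruned = copy.deepcopy(subtrees[k])
    pruned.pruned = True
    return pruned


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP with disease (label 1) as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def evaluate(tree: TreeModel, X, y) -> ConfusionCounts:
    """Confusion counts of a fitted tree on held-out data."""
    y = np.asarray(y).astype(int)
    pred = tree.predict(X)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Classification metrics from confusion counts.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), ACC = (TP+TN)/total,
    TNR = TN/(FP+TN), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    FDR = FP/(FP+TP) and error% = 100·(FN+FP)/total.  A zero denominator
    yields ``nan`` rather than an exception.
    """

    def ratio(a, b):
        return a / b if b else float("nan")

    return {
        "TPR": ratio(c.tp, c.tp + c.fn),
        "FPR": ratio(c.fp, c.fp + c.tn),
        "ACC": ratio(c.tp + c.tn, c.total),
        "TNR": ratio(c.tn, c.fp + c.tn),
        "PPV": ratio(c.tp, c.tp + c.fp),
        "NPV": ratio(c.tn, c.tn + c.fn),
        "FDR": ratio(c.fp, c.fp + c.tp),
        "error_pct": ratio(100.0 * (c.fn + c.fp), c.total),
    }
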