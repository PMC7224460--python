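"""A deterministic binary CART classifier with risk-based importance.

Splits maximise the reduction in node risk, where the risk of a node is
its sample-weight fraction times its impurity (Gini by default, or the
mean squared error of the 0/1 labels). Ties in split gain are broken by
the lowest feature index, then the lowest threshold, so a feature that
duplicates an earlier one can never be chosen — which makes predictor
importance exactly zero for never-split features.

Predictor importance follows the convention of summing, per feature,
the risk reductions of all branch nodes splitting on it, then dividing
by the total number of branch nodes of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class Node:
    n: int
    impurity: float
    risk: float
    label: int
    feature: int | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _impurity(n1: float, n: float, criterion: str) -> float:
    """Impurity of a node with n samples of which n1 are class 1."""
    if n == 0:
        return 0.0
    p = n1 / n
    if criterion == "gini":
        return 2.0 * p * (1.0 - p)
    if criterion == "mse":
        return p * (1.0 - p)  # variance of 0/1 labels
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class CART:
    """Binary classification tree for 0/1 labels.

    Parameters
    ----------
    criterion : {"gini", "mse"}
        Node impurity; "mse" is the mean squared error of the labels.
    min_split : int
        Minimum node size to attempt a split.
    min_leaf : int
        Minimum samples per child.
    max_depth : int or None
    """

    criterion: str = "gini"
    min_split: int = 10
    min_leaf: int = 1
    max_depth: int | None = None
    root: Node | None = field(default=None, repr=False)
    n_features_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CART":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if len(X) == 0:
            raise ValueError("empty training set")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        self.n_features_ = X.shape[1]
        self._n_total = len(y)
        self.root = self._grow(X, y, depth=0)
        return self

    def _make_node(self, y: np.ndarray) -> Node:
        n = len(y)
        n1 = int(y.sum())
        imp = _impurity(n1, n, self.criterion)
        label = 1 if n1 * 2 > n else 0  # tie -> 0
        return Node(n=n, impurity=imp, risk=(n / self._n_total) * imp,
                    label=label)

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> Node:
        node = self._make_node(y)
        if (
            node.impurity <= 0.0
            or node.n < self.min_split
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        best = self._best_split(X, y, node)
        if best is None:
            return node
        j, thr = best
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _best_split(self, X: np.ndarray, y: np.ndarray,
                    node: Node) -> tuple[int, float] | None:
        n = len(y)
        w = 1.0 / self._n_total
        best_gain = _EPS
        best: tuple[int, float] | None = None
        for j in range(X.shape[1]):  # ascending: earliest feature wins ties
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y[order]
            c1 = np.cumsum(ys)  # class-1 count left of each cut
            # candidate cuts between distinct consecutive values
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            for i in distinct:
                n_l = i + 1
                n_r = n - n_l
                if n_l < self.min_leaf or n_r < self.min_leaf:
                    continue
                risk_l = w * n_l * _impurity(c1[i], n_l, self.criterion)
                risk_r = w * n_r * _impurity(c1[-1] - c1[i], n_r, self.criterion)
                gain = node.risk - risk_l - risk_r
                # strict '>' keeps the earliest feature / lowest threshold
                if gain > best_gain + _EPS:
                    best_gain = gain
                    best = (j, (xs[i] + xs[i + 1]) / 2.0)
        return best

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root is None:
            raise ValueError("tree not fitted")
        X = np.asarray(X, float)
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold \
                    else node.right
            out[i] = node.label
        return out

    # -- structure queries ---------------------------------------------------

    def branch_nodes(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root] if self.root else []
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    @property
    def n_branch_nodes(self) -> int:
        return len(self.branch_nodes())

    def total_risk_reduction(self) -> float:
        return sum(b.risk - b.left.risk - b.right.risk
                   for b in self.branch_nodes())

    def predictor_importance(self) -> np.ndarray:
        """Per-feature importance: summed split risk reductions divided
        by the number of branch nodes; exactly 0 for unused features."""
        imp = np.zeros(self.n_features_)
        branches = self.branch_nodes()
        if not branches:
            return imp
        for b in branches:
            imp[b.feature] += b.risk - b.left.risk - b.right.risk
        return imp / len(branches)


def fit_cart(X: np.ndarray, y: np.ndarray, criterion: str = "gini",
             min_split: int = 10, min_leaf: int = 1,
             max_depth: int | None = None) -> CART:
    """Fit a deterministic CART on 0/1 labels."""
    return CART(criterion=criterion, min_split=min_split,
                min_leaf=min_leaf, max_depth=max_depth).fit(X, y)
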