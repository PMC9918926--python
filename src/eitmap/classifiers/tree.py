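"""Classification trees (CART) grown by greedy Gini-minimizing splits.

Splits are single-feature thresholds at midpoints between consecutive
distinct sorted values; the chosen split minimizes the size-weighted mean
child Gini impurity.  Ties break toward the lowest feature index, then
the lowest threshold.  Growth stops at the depth bound, the minimum leaf
size, or when no split reduces impurity.  Leaves predict the class-1
fraction of their training samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .._errors import ValidationError

__all__ = ["gini_impurity", "CARTClassifier", "CARTResults", "TreeNode", "Leaf"]


def gini_impurity(counts) -> float:
    """Gini index 1 - sum_d p_d^2 of a node's class counts."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or c.sum() == 0:
        raise ValidationError("class counts must be nonnegative and not all zero")
    p = c / c.sum()
    return float(1.0 - np.sum(p**2))


@dataclass
class Leaf:
    counts: tuple  # (n0, n1)
    fraction: float  # class-1 fraction


@dataclass
class TreeNode:
    feature: int
    threshold: float
    left: Union["TreeNode", Leaf]
    right: Union["TreeNode", Leaf]


class CARTClassifier:
    """Binary classification tree model.

    Parameters
    ----------
    endog : (n,) binary labels
    exog : (n, m) features
    max_depth : int
    min_samples_leaf : int
    min_impurity_decrease : float
        A split must reduce the size-weighted impurity by more than this.
    """

    def __init__(self, endog, exog, max_depth: int = 12,
                 min_samples_leaf: int = 5, min_impurity_decrease: float = 0.0):
        y = np.asarray(endog).ravel().astype(np.int64)
        X = np.asarray(exog, dtype=float)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("endog must be binary 0/1")
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValidationError("exog must be n x m aligned with endog")
        if len(y) < 2 * min_samples_leaf:
            raise ValidationError("need n >= 2 * min_samples_leaf")
        self.endog, self.exog = y, X
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_impurity_decrease = min_impurity_decrease

    def fit(self) -> "CARTResults":
        idx = np.arange(len(self.endog))
        root = self._grow(idx, depth=0)
        return CARTResults(self, root)

    # ------------------------------------------------------------------

    def _grow(self, idx: np.ndarray, depth: int):
        y = self.endog[idx]
        n = len(idx)
        n1 = int(y.sum())
        leaf = Leaf((n - n1, n1), n1 / n)
        if depth >= self.max_depth or n < 2 * self.min_samples_leaf or n1 in (0, n):
            return leaf
        found = self.best_split(self.exog[idx], y)
        if found is None:
            return leaf
        feature, threshold, child_gini = found
        parent_gini = gini_impurity((n - n1, n1))
        if parent_gini - child_gini <= self.min_impurity_decrease + 1e-15:
            return leaf
        mask = self.exog[idx, feature] <= threshold
        return TreeNode(
            feature,
            threshold,
            self._grow(idx[mask], depth + 1),
            self._grow(idx[~mask], depth + 1),
        )

    def best_split(self, X: np.ndarray, y: np.ndarray) -> Optional[tuple]:
        """Minimize size-weighted child Gini over all (feature, midpoint) pairs.

        Returns (feature, threshold, weighted child gini) or None when no
        candidate respects the minimum leaf size.
        """
        n, m = X.shape
        mleaf = self.min_samples_leaf
        best = None
        for j in range(m):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y[order]
            pos = np.cumsum(ys)
            i = np.arange(1, n)  # left sizes
            valid = (xs[1:] > xs[:-1]) & (i >= mleaf) & (n - i >= mleaf)
            if not valid.any():
                continue
            i = i[valid]
            p1l = pos[i - 1] / i
            p1r = (pos[-1] - pos[i - 1]) / (n - i)
            gl = 1 - p1l**2 - (1 - p1l) ** 2
            gr = 1 - p1r**2 - (1 - p1r) ** 2
            weighted = (i * gl + (n - i) * gr) / n
            k = int(np.argmin(weighted))  # first minimum = lowest threshold
            thr = 0.5 * (xs[i[k] - 1] + xs[i[k]])
            if best is None or weighted[k] < best[2]:
                best = (j, float(thr), float(weighted[k]))
        return best


@dataclass
class CARTResults:
    """Fitted classification tree."""

    model: CARTClassifier
    root: Union[TreeNode, Leaf]

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = self.root
            while isinstance(node, TreeNode):
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.fraction
        return out

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def depth(self) -> int:
        def d(node):
            if isinstance(node, Leaf):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def n_leaves(self) -> int:
        def c(node):
            if isinstance(node, Leaf):
                return 1
            return c(node.left) + c(node.right)

        return c(self.root)

    def summary(self) -> str:
        return (
            "CART classification tree\n"
            f"  depth:       {self.depth()} (max {self.model.max_depth})\n"
            f"  leaves:      {self.n_leaves()}\n"
            f"  min leaf:    {self.model.min_samples_leaf}"
        )
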