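"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: closed-form potentials, unpenalized Newton
logistic fits, exhaustive split enumeration, pair-counting AUC.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def disk_two_point_potential(points, src, sink, current, sigma):
    """Closed-form potential of two boundary point sources on a disk.

    For a homogeneous disk, a boundary point source coincides with its
    image charge, so the interior potential is
    u(x) = (I / (pi sigma)) * ln(|x - sink| / |x - src|) up to a constant.
    """
    points = np.atleast_2d(points)
    d_src = np.linalg.norm(points - src, axis=1)
    d_sink = np.linalg.norm(points - sink, axis=1)
    return current / (np.pi * sigma) * (np.log(d_sink) - np.log(d_src))


def irls_logistic(X, y, max_iter=200, tol=1e-12):
    """Unpenalized logistic MLE by plain Newton/IRLS (with intercept)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        p = expit(X1 @ beta)
        W = p * (1 - p)
        g = X1.T @ (y - p)
        H = (X1 * W[:, None]).T @ X1
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta  # [intercept, coefs...]


def brute_force_best_split(X, y, min_leaf=1):
    """Exhaustive search over all (feature, midpoint) splits.

    Returns (feature, threshold, weighted child Gini) minimizing the
    size-weighted child impurity, ties toward lowest feature index then
    lowest threshold; None if no split respects min_leaf.
    """
    n, m = X.shape

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = labels.mean()
        return 1 - p**2 - (1 - p) ** 2

    best = None
    for j in range(m):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            w = (nl * gini(y[left]) + (n - nl) * gini(y[~left])) / n
            if best is None or w < best[2] - 1e-15:
                best = (j, thr, w)
    return best


def pair_counting_auc(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = len(pos) * len(neg)
    conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return conc / total
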