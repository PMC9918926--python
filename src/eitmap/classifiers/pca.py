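"""Principal component analysis for de-correlating voltage features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._errors import ValidationError

__all__ = ["PCATransform", "fit_pca"]


@dataclass
class PCATransform:
    """Centered orthonormal projection onto leading variance directions."""

    center: np.ndarray
    loadings: np.ndarray  # (m, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # all m ratios, nonincreasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) @ self.loadings

    def inverse_transform(self, T) -> np.ndarray:
        T = np.atleast_2d(np.asarray(T, dtype=float))
        return T @ self.loadings.T + self.center

    def cumulative_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def fit_pca(X, retain=0.9999) -> PCATransform:
    """Fit PCA retaining a component count (int) or variance fraction.

    Components are eigenvectors of the sample covariance ordered by
    decreasing eigenvalue; each column's sign is fixed so its
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA needs an n x m matrix with n >= 2")
    center = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - center, full_matrices=False)
    var = s**2
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    if isinstance(retain, (int, np.integer)) and not isinstance(retain, bool):
        k = int(retain)
        if not 1 <= k <= len(s):
            raise ValidationError(f"component count must be in [1, {len(s)}]")
    else:
        frac = float(retain)
        if not 0 < frac <= 1:
            raise ValidationError("retain fraction must lie in (0, 1]")
        k = int(np.searchsorted(np.cumsum(ratios), frac - 1e-12) + 1)
        k = min(k, len(s))
    V = Vt[:k].T
    # Deterministic sign: largest-|entry| of each loading made positive.
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return PCATransform(center=center, loadings=V, explained_variance_ratio=ratios)
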