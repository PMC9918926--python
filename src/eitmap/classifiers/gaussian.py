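"""Gaussian discriminant classifiers: LDA, QDA and regularized variants.

Both classes are modeled as multivariate normals N(mu_k, Sigma_k) with
priors pi_k = n_k / n.  LDA pools the covariance (divisor n - 2 for two
classes), QDA keeps per-class covariances (divisor n_k - 1).  Two
regularizations are available:

* class-toward-pooled shrinkage  Sigma_k(a) = a Sigma_k + (1 - a) Sigma,
* pooled-toward-spherical shrinkage  Sigma(g) = g Sigma + (1 - g) s2 I
  with s2 = trace(Sigma) / m (the average eigenvalue), so g = 0 yields a
  spherical covariance of matched scale.

The default RDA mode is LDA with the spherical shrinkage, the shrinkage
weight selected by cross-validated accuracy on a small grid.  Posteriors
come from the discriminant scores through a max-subtracted softmax, which
is algebraically Bayes' rule with Gaussian densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .._errors import ConfigurationError, SolverError, ValidationError

__all__ = ["GaussianDiscriminant", "GaussianDiscriminantResults"]

_MODES = ("lda", "qda", "rda", "rda-alpha")


class GaussianDiscriminant:
    """Two-class Gaussian discriminant model.

    Parameters
    ----------
    endog : (n,) binary labels
    exog : (n, m) features
    mode : {'lda', 'qda', 'rda', 'rda-alpha'}
        'rda' is LDA with spherical shrinkage of the pooled covariance;
        'rda-alpha' shrinks each class covariance toward the pooled one.
    """

    def __init__(self, endog, exog, mode: str = "lda"):
        if mode not in _MODES:
            raise ConfigurationError(f"unknown mode {mode!r}; choose from {_MODES}")
        y = np.asarray(endog).ravel()
        X = np.asarray(exog, dtype=float)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("endog must be binary 0/1")
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValidationError("exog must be n x m aligned with endog")
        self.endog = y.astype(int)
        self.exog = X
        self.mode = mode

    def fit(
        self,
        alpha: Optional[float] = None,
        gamma: Optional[float] = None,
        gamma_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
        cv_folds: int = 5,
        seed: int = 0,
    ) -> "GaussianDiscriminantResults":
        y, X = self.endog, self.exog
        n, m = X.shape
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        if min(n0, n1) < 2:
            raise ValidationError("each class needs >= 2 samples for covariance estimation")
        priors = np.array([n0 / n, n1 / n])
        mu = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
        dev = [X[y == k] - mu[k] for k in (0, 1)]
        pooled = (dev[0].T @ dev[0] + dev[1].T @ dev[1]) / (n - 2)
        per_class = [dev[k].T @ dev[k] / (len(dev[k]) - 1) for k in (0, 1)]

        if self.mode == "lda":
            covs, shared = [pooled, pooled], True
        elif self.mode == "qda":
            if alpha is not None:
                covs = [alpha * per_class[k] + (1 - alpha) * pooled for k in (0, 1)]
            else:
                covs = per_class
            shared = False
        elif self.mode == "rda-alpha":
            a = 0.5 if alpha is None else float(alpha)
            if not 0 <= a <= 1:
                raise ValidationError("alpha must lie in [0, 1]")
            covs = [a * per_class[k] + (1 - a) * pooled for k in (0, 1)]
            shared = False
        else:  # rda: LDA + spherical shrinkage
            if gamma is None:
                gamma = self._select_gamma(gamma_grid, cv_folds, seed)
            if not 0 <= gamma <= 1:
                raise ValidationError("gamma must lie in [0, 1]")
            cov = _spherical_shrink(pooled, gamma)
            covs, shared = [cov, cov], True

        return GaussianDiscriminantResults(
            model=self,
            priors=priors,
            means=mu,
            covariances=[np.asarray(c) for c in covs],
            pooled_cov=pooled,
            class_covs=per_class,
            shared=shared,
            alpha=alpha,
            gamma=gamma,
        )

    def _select_gamma(self, grid, folds: int, seed: int) -> float:
        """Pick the shrinkage weight minimizing CV classification error."""
        y, X = self.endog, self.exog
        n = len(y)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        fold_id = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(perm, folds)):
            fold_id[chunk] = k
        best_g, best_acc = None, -np.inf
        for g in grid:
            accs = []
            for k in range(folds):
                tr, te = fold_id != k, fold_id == k
                if len(np.unique(y[tr])) < 2 or min(np.bincount(y[tr])) < 2:
                    continue
                try:
                    res = GaussianDiscriminant(y[tr], X[tr], mode="rda").fit(gamma=g)
                except (SolverError, np.linalg.LinAlgError):
                    continue
                accs.append(np.mean(res.predict(X[te]) == y[te]))
            acc = np.mean(accs) if accs else -np.inf
            # ties toward stronger shrinkage (smaller gamma): grid ascends,
            # strict > keeps the earlier (smaller) gamma.
            if acc > best_acc:
                best_acc, best_g = acc, float(g)
        if best_g is None:
            raise SolverError("RDA gamma selection failed on every fold")
        return best_g


def _spherical_shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    m = cov.shape[0]
    s2 = np.trace(cov) / m
    return gamma * cov + (1 - gamma) * s2 * np.eye(m)


@dataclass
class GaussianDiscriminantResults:
    """Fitted Gaussian discriminant: priors, means, covariance factorizations."""

    model: GaussianDiscriminant
    priors: np.ndarray
    means: np.ndarray
    covariances: list
    pooled_cov: np.ndarray
    class_covs: list
    shared: bool
    alpha: Optional[float] = None
    gamma: Optional[float] = None
    _chol: list = field(default=None, repr=False)
    _logdet: list = field(default=None, repr=False)

    def __post_init__(self):
        self._chol, self._logdet = [], []
        for k, cov in enumerate(self.covariances):
            try:
                c = cho_factor(cov, lower=True)
            except np.linalg.LinAlgError as exc:
                raise SolverError(
                    f"class-{k} covariance is not positive definite; "
                    "use shrinkage (gamma < 1) or PCA to reduce dimension"
                ) from exc
            self._chol.append(c)
            self._logdet.append(2.0 * np.sum(np.log(np.diag(c[0]))))

    @property
    def mode(self) -> str:
        return self.model.mode

    def discriminant_scores(self, X) -> np.ndarray:
        """(n, 2) array of delta_k(x); decision is argmax over k.

        LDA (shared covariance): delta_k = log pi_k + x' S^-1 mu_k
        - mu_k' S^-1 mu_k / 2.  QDA-type: delta_k = log pi_k
        - (x - mu_k)' S_k^-1 (x - mu_k) / 2 - log det S_k / 2.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValidationError("feature length mismatch")
        out = np.empty((X.shape[0], 2))
        for k in (0, 1):
            if self.shared:
                w = cho_solve(self._chol[k], self.means[k])
                out[:, k] = (
                    np.log(self.priors[k]) + X @ w - 0.5 * float(self.means[k] @ w)
                )
            else:
                d = X - self.means[k]
                sol = cho_solve(self._chol[k], d.T).T
                maha = np.einsum("ij,ij->i", d, sol)
                out[:, k] = np.log(self.priors[k]) - 0.5 * maha - 0.5 * self._logdet[k]
        return out

    def posterior(self, X) -> np.ndarray:
        """P(Y=1 | x) via max-subtracted softmax over discriminant scores."""
        d = self.discriminant_scores(X)
        if not self.shared:
            # softmax over QDA scores is exactly Bayes with Gaussian
            # densities (the -m/2 log 2pi terms cancel).
            pass
        z = d - d.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e[:, 1] / e.sum(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        return self.posterior(X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Thresholded posterior; at 0.5 equals argmax_k delta_k."""
        return (self.posterior(X) >= threshold).astype(np.uint8)

    def summary(self) -> str:
        lines = [
            f"Gaussian discriminant ({self.mode.upper()})",
            f"  priors:      pi0={self.priors[0]:.4f}, pi1={self.priors[1]:.4f}",
            f"  features:    {self.means.shape[1]}",
            f"  covariance:  {'pooled' if self.shared else 'per-class'}",
        ]
        if self.gamma is not None:
            lines.append(f"  gamma (spherical shrinkage): {self.gamma:.3f}")
        if self.alpha is not None:
            lines.append(f"  alpha (toward-pooled shrinkage): {self.alpha:.3f}")
        return "\n".join(lines)
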