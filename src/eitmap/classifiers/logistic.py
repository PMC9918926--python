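"""Penalized logistic regression with the elastic-net penalty.

The voltage features of an EIT frame are strongly collinear, so the
per-element logistic classifiers are fitted as penalized maximum
likelihood: minimize the mean negative log-likelihood plus
``lam * (alpha * |beta|_1 + (1 - alpha)/2 * |beta|_2^2)`` with an
unpenalized intercept.  ``alpha = 1`` is the LASSO, ``alpha = 0`` ridge
(Tikhonov) regression.  The solver is glmnet-style: an outer IRLS
quadratic approximation with inner cyclic coordinate descent and
soft-thresholding, warm-started along a decreasing lambda path.  The
penalty weight is selected by K-fold cross-validated accuracy at the 0.5
threshold, ties resolved toward the stronger penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .._errors import OptimizationError, ValidationError

__all__ = ["ElasticNetLogit", "ElasticNetLogitResults", "predict_proba_logistic"]

_MIN_WEIGHT = 1e-6


def _soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


class ElasticNetLogit:
    """Elastic-net penalized logistic model for one binary target.

    Parameters
    ----------
    endog : (n,) binary array
        Element labels.
    exog : (n, m) array
        Measurement frames (features).
    alpha : float in [0, 1]
        L1/L2 mixing; 1 = LASSO, 0 = ridge.
    standardize : bool
        Center/scale columns before penalization (coefficients are
        reported on the original scale either way).
    """

    def __init__(self, endog, exog, alpha: float = 0.5, standardize: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("exog must be n x m with n matching endog")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("endog must be binary 0/1")
        if not 0.0 <= alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        self.endog = y
        self.exog = X
        self.alpha = float(alpha)
        self.standardize = standardize
        self._mean = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
        sd = X.std(axis=0) if standardize else np.ones(X.shape[1])
        self._scale = np.where(sd > 0, sd, 1.0)
        self._Xs = (X - self._mean) / self._scale

    # ------------------------------------------------------------------

    def lambda_max(self) -> float:
        """Smallest lambda at which all LASSO coefficients are zero."""
        n = len(self.endog)
        ybar = self.endog.mean()
        score = np.abs(self._Xs.T @ (self.endog - ybar)) / n
        return float(score.max() / max(self.alpha, 1e-3))

    def lambda_grid(self, n_lambdas: int = 50, decades: float = 4.0) -> np.ndarray:
        lmax = self.lambda_max()
        return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambdas)

    def fit(self, lam: float, start: Optional[np.ndarray] = None,
            tol: float = 1e-6, max_iter: int = 500) -> "ElasticNetLogitResults":
        """Penalized MLE at one penalty weight."""
        if lam < 0:
            raise ValidationError("lam must be >= 0")
        coef = self._irls_cd(lam, start=start, tol=tol, max_iter=max_iter, strict=True)
        return self._results(lam, coef)

    def fit_cv(self, folds: int = 10, lam_grid: Optional[np.ndarray] = None,
               seed: int = 0, tol: float = 1e-6) -> "ElasticNetLogitResults":
        """Fit the lambda path and select by K-fold CV accuracy."""
        n = len(self.endog)
        if n < 2 * folds:
            raise ValidationError("need n >= 2K samples for K-fold CV")
        if lam_grid is None:
            lam_grid = self.lambda_grid()
        lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        fold_id = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(perm, folds)):
            fold_id[chunk] = k
        acc = np.zeros((folds, len(lam_grid)))
        for k in range(folds):
            tr, te = fold_id != k, fold_id == k
            sub = ElasticNetLogit(self.endog[tr], self.exog[tr],
                                  alpha=self.alpha, standardize=self.standardize)
            coef = None
            for j, lam in enumerate(lam_grid):
                coef = sub._irls_cd(lam, start=coef, tol=tol)
                p = expit(coef[0] + sub._transform(self.exog[te]) @ coef[1:])
                acc[k, j] = np.mean((p >= 0.5) == (self.endog[te] == 1))
        mean_acc = acc.mean(axis=0)
        # Ties toward larger lambda: the grid is descending, argmax takes
        # the first (largest-penalty) maximizer.
        best = int(np.argmax(mean_acc))
        coef, path = None, {}
        for j, lam in enumerate(lam_grid):
            coef = self._irls_cd(lam, start=coef, tol=tol)
            if j == best:
                break
        res = self._results(float(lam_grid[best]), coef)
        res.cv_record = {
            "lam_grid": lam_grid.tolist(),
            "fold_accuracy": acc.tolist(),
            "mean_accuracy": mean_acc.tolist(),
            "selected_index": best,
            "folds": folds,
            "seed": int(seed),
        }
        _ = path
        return res

    # ------------------------------------------------------------------

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self._mean) / self._scale

    def _irls_cd(self, lam: float, start=None, tol: float = 1e-6,
                 max_iter: int = 100, inner_iter: int = 500,
                 strict: bool = False) -> np.ndarray:
        """IRLS + Gram-matrix coordinate descent in the standardized space.

        Returns the (m+1,) vector [intercept, beta] on the standardized
        scale.  With ``strict`` the KKT stationarity conditions must hold
        to ``tol`` or OptimizationError is raised; path/CV fits run with
        a capped budget instead (warm starts keep them accurate).
        """
        X, y = self._Xs, self.endog
        n, m = X.shape
        coef = np.zeros(m + 1) if start is None else start.copy()
        l1 = lam * self.alpha
        l2 = lam * (1.0 - self.alpha)
        for _ in range(max_iter):
            z = coef[0] + X @ coef[1:]
            p = expit(z)
            w = np.clip(p * (1 - p), _MIN_WEIGHT, None)
            resp = z + (y - p) / w
            coef_new = self._wls_cd(X, resp, w, coef, l1, l2, inner_iter)
            step = np.max(np.abs(coef_new - coef))
            coef = coef_new
            if step < 0.1 * tol * max(1.0, np.abs(coef).max()):
                break
        if strict:
            viol = self._kkt_violation(coef, l1, l2)
            if viol > tol * max(1.0, np.abs(coef).max()):
                raise OptimizationError(
                    "elastic-net logistic fit did not converge",
                    diagnostics={"lam": lam, "kkt": viol},
                )
        return coef

    def _wls_cd(self, X, resp, w, coef, l1, l2, inner_iter) -> np.ndarray:
        """Solve the penalized weighted least-squares subproblem.

        A few coordinate-descent sweeps on the weighted Gram matrix fix
        the working set, then the KKT system restricted to the active
        coordinates is solved exactly; inactive-coordinate violations
        re-enter the set until stationarity.  O(m) per coordinate and a
        handful of m x m solves, independent of n.
        """
        n, m = X.shape
        coef = coef.copy()
        wsum = w.sum()
        Xw = X * w[:, None]
        A = (Xw.T @ X) / n
        b = (Xw.T @ resp) / n
        xw_mean = Xw.sum(axis=0) / n
        wr_mean = (w * resp).sum() / n
        diag = np.diag(A).copy()
        beta = coef[1:]
        b0 = coef[0]

        def sweep():
            nonlocal b0
            delta = 0.0
            new0 = (wr_mean - xw_mean @ beta) * n / wsum
            delta = abs(new0 - b0)
            b0 = new0
            for j in range(m):
                old = beta[j]
                rho = b[j] - b0 * xw_mean[j] - A[j] @ beta + diag[j] * old
                new = _soft_threshold(rho, l1) / (diag[j] + l2)
                if new != old:
                    beta[j] = new
                    delta = max(delta, abs(new - old))
            return delta

        for _ in range(3):
            if sweep() < 1e-12:
                break
        for _ in range(inner_iter):
            active = np.nonzero(beta)[0]
            k = len(active)
            signs = np.sign(beta[active])
            # Bordered system: intercept row + active coordinates.
            M = np.empty((k + 1, k + 1))
            M[0, 0] = wsum / n
            M[0, 1:] = M[1:, 0] = xw_mean[active]
            M[1:, 1:] = A[np.ix_(active, active)] + l2 * np.eye(k)
            rhs = np.concatenate([[wr_mean], b[active] - l1 * signs])
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            b0 = sol[0]
            new_beta = np.zeros(m)
            new_beta[active] = sol[1:]
            flipped = active[np.sign(new_beta[active]) * signs < 0]
            if len(flipped):
                new_beta[flipped] = 0.0
                beta = new_beta
                continue
            beta = new_beta
            grad = b - b0 * xw_mean - A @ beta
            inactive = np.setdiff1d(np.arange(m), np.nonzero(beta)[0], assume_unique=False)
            if len(inactive) == 0:
                break
            viol = np.abs(grad[inactive]) - l1
            worst = int(np.argmax(viol))
            if viol[worst] <= 1e-12:
                break
            j = inactive[worst]
            beta[j] = np.sign(grad[j]) * 1e-12  # admit with the gradient's sign
        coef[0] = b0
        coef[1:] = beta
        return coef

    def _kkt_violation(self, coef: np.ndarray, l1: float, l2: float) -> float:
        """Max violation of the penalized-MLE stationarity conditions."""
        X, y = self._Xs, self.endog
        n = len(y)
        p = expit(coef[0] + X @ coef[1:])
        g = -(X.T @ (y - p)) / n + l2 * coef[1:]
        g0 = -np.mean(y - p)
        viol = abs(g0)
        active = coef[1:] != 0
        if active.any():
            viol = max(viol, np.max(np.abs(g[active] + l1 * np.sign(coef[1:][active]))))
        if (~active).any():
            viol = max(viol, np.max(np.clip(np.abs(g[~active]) - l1, 0, None)))
        return float(viol)

    def _results(self, lam: float, coef: np.ndarray) -> "ElasticNetLogitResults":
        beta = coef[1:] / self._scale
        intercept = coef[0] - float(np.dot(coef[1:], self._mean / self._scale))
        return ElasticNetLogitResults(self, lam, intercept, beta, coef.copy())


@dataclass
class ElasticNetLogitResults:
    """Fitted elastic-net logistic model (coefficients on the original scale)."""

    model: ElasticNetLogit
    lam: float
    intercept: float
    params: np.ndarray
    _coef_std: np.ndarray = field(repr=False, default=None)
    cv_record: dict = field(default_factory=dict)

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.params):
            raise ValidationError("feature length mismatch")
        return self.intercept + X @ self.params

    def predict_proba(self, X) -> np.ndarray:
        """P(y=1 | x) = e^z / (1 + e^z), numerically stable for |z| <= ~700."""
        return expit(self.linear_predictor(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.params))

    def summary(self) -> str:
        lines = [
            "Elastic-net logistic regression",
            f"  alpha (L1 mix):     {self.alpha:.3f}",
            f"  lambda:             {self.lam:.6g}",
            f"  intercept:          {self.intercept:.6g}",
            f"  nonzero coefs:      {self.n_nonzero()} / {len(self.params)}",
        ]
        if self.cv_record:
            j = self.cv_record["selected_index"]
            lines.append(
                f"  CV accuracy:        {self.cv_record['mean_accuracy'][j]:.4f} "
                f"({self.cv_record['folds']}-fold)"
            )
        return "\n".join(lines)


def predict_proba_logistic(results: ElasticNetLogitResults, x) -> np.ndarray:
    """Functional alias for Results.predict_proba."""
    return results.predict_proba(x)
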