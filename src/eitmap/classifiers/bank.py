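"""Per-element classifier banks: one trained model per mesh element.

Reconstruction works element by element: for mesh element e the bank
holds a classifier trained on (X, Y[:, e]) that maps a 32-component
voltage frame to the probability that element e lies inside the
inclusion.  Elements that are (almost) never covered by an inclusion get
an explicit constant model predicting their observed base rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._errors import ConfigurationError, SolverError, ValidationError
from ..phantoms import Dataset
from .gaussian import GaussianDiscriminant
from .logistic import ElasticNetLogit
from .pca import PCATransform, fit_pca
from .tree import CARTClassifier

__all__ = ["METHODS", "ConstantModel", "ElementBank", "ElementBankResults"]

#: Supported method tags and their per-element family.
METHODS = (
    "lr-elastic",
    "lr-ridge",
    "lr-lasso",
    "lda",
    "qda",
    "rda",
    "lda-pca",
    "qda-pca",
    "cart",
)

_LR_ALPHA = {"lr-elastic": 0.5, "lr-ridge": 0.0, "lr-lasso": 1.0}


@dataclass
class ConstantModel:
    """Degenerate-element sentinel: predicts the observed base rate."""

    rate: float

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.rate)


class ElementBank:
    """Model: train one classifier of a chosen family per mesh element.

    Parameters
    ----------
    dataset : Dataset or (X, Y) pair
        Frames and per-element binary labels.
    method : str
        One of ``METHODS``.
    pca_retain : int or float
        Shared-PCA retention (component count or variance fraction) for
        the ``*-pca`` variants.
    min_positive : int, optional
        Elements with fewer positive samples get the constant sentinel.
        Defaults per family: 2 for LDA/RDA, reduced-dim + 2 for QDA
        variants, 10 for logistic (so CV folds see positives), 1 for CART.
    cv_folds : int
        K for the logistic lambda selection and RDA gamma selection.
    """

    def __init__(
        self,
        dataset,
        method: str = "qda-pca",
        pca_retain=0.9999,
        min_positive: Optional[int] = None,
        cv_folds: int = 10,
        n_lambdas: int = 50,
        tree_max_depth: int = 12,
        tree_min_leaf: int = 5,
        rda_gamma: Optional[float] = None,
    ):
        if method not in METHODS:
            raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
        if isinstance(dataset, Dataset):
            self.X, self.Y = dataset.X, dataset.Y
            self.metadata = dict(dataset.metadata)
        else:
            self.X, self.Y = (np.asarray(a) for a in dataset)
            self.metadata = {}
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError("X and Y row counts differ")
        self.method = method
        self.pca_retain = pca_retain
        self.min_positive = min_positive
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.tree_max_depth = tree_max_depth
        self.tree_min_leaf = tree_min_leaf
        self.rda_gamma = rda_gamma

    def fit(self, seed: int = 0, verbose: bool = False) -> "ElementBankResults":
        X, Y = self.X, self.Y
        n, E = Y.shape
        pca = None
        F = X
        if self.method.endswith("-pca"):
            pca = fit_pca(X, retain=self.pca_retain)
            F = pca.transform(X)
        dim = F.shape[1]
        min_pos = self.min_positive
        if min_pos is None:
            if self.method in ("qda", "qda-pca"):
                min_pos = dim + 2
            elif self.method in ("lda", "rda", "lda-pca"):
                min_pos = 4
            elif self.method.startswith("lr-"):
                min_pos = max(10, self.cv_folds)
            else:
                min_pos = 1
        models = []
        n_constant = 0
        for e in range(E):
            y = Y[:, e].astype(int)
            pos = int(y.sum())
            if pos < min_pos or n - pos < min_pos:
                models.append(ConstantModel(pos / n))
                n_constant += 1
                continue
            try:
                models.append(self._fit_one(F, y, seed=seed ^ (e * 2654435761 % 2**31)))
            except (SolverError, np.linalg.LinAlgError):
                models.append(ConstantModel(pos / n))
                n_constant += 1
            if verbose and (e + 1) % 200 == 0:
                print(f"  trained {e + 1}/{E} elements")
        return ElementBankResults(
            bank=self,
            models=models,
            pca=pca,
            n_constant=n_constant,
            seed=seed,
            metadata=dict(self.metadata, method=self.method),
        )

    def _fit_one(self, F: np.ndarray, y: np.ndarray, seed: int):
        m = self.method
        if m.startswith("lr-"):
            model = ElasticNetLogit(y, F, alpha=_LR_ALPHA[m])
            return model.fit_cv(folds=self.cv_folds,
                                lam_grid=model.lambda_grid(self.n_lambdas), seed=seed)
        if m in ("lda", "lda-pca"):
            return GaussianDiscriminant(y, F, mode="lda").fit()
        if m in ("qda", "qda-pca"):
            return GaussianDiscriminant(y, F, mode="qda").fit()
        if m == "rda":
            return GaussianDiscriminant(y, F, mode="rda").fit(
                gamma=self.rda_gamma, seed=seed)
        if m == "cart":
            return CARTClassifier(
                y, F, max_depth=self.tree_max_depth,
                min_samples_leaf=self.tree_min_leaf,
            ).fit()
        raise ConfigurationError(f"unknown method {m!r}")  # pragma: no cover


@dataclass
class ElementBankResults:
    """Fitted bank: per-element models plus the shared PCA (if any)."""

    bank: ElementBank
    models: list
    pca: Optional[PCATransform]
    n_constant: int
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.models)

    @property
    def method(self) -> str:
        return self.bank.method

    def predict_proba(self, frames) -> np.ndarray:
        """Per-element inclusion probabilities for one or more frames.

        Returns (E,) for a single frame or (n, E) for a stack.
        """
        A = np.atleast_2d(np.asarray(frames, dtype=float))
        F = self.pca.transform(A) if self.pca is not None else A
        out = np.empty((A.shape[0], self.n_elements))
        for e, model in enumerate(self.models):
            out[:, e] = model.predict_proba(F)
        return out[0] if np.asarray(frames).ndim == 1 else out

    def summary(self) -> str:
        return (
            "Element classifier bank\n"
            f"  method:            {self.method}\n"
            f"  elements:          {self.n_elements}\n"
            f"  constant models:   {self.n_constant}\n"
            f"  shared PCA comps:  "
            f"{self.pca.n_components if self.pca is not None else '-'}\n"
            f"  training samples:  {self.bank.X.shape[0]}"
        )
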