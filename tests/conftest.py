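"""Shared fixtures: meshes, datasets and the scaled end-to-end artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from eitmap.classifiers import ElementBank
from eitmap.evaluation import fit_report, reconstruct
from eitmap.mesh import build_torso_mesh
from eitmap.phantoms import Dataset, generate_dataset
from eitmap.pipeline import holdout_split
from eitmap.protocol import default_protocol

DATA_DIR = Path(__file__).parent / "data"

#: Edge length giving a ~535-element torso mesh (the scaled-down study mesh).
COARSE_EDGE = 0.0145


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_torso_mesh(target_edge_length=COARSE_EDGE)


@pytest.fixture(scope="session")
def small_dataset(coarse_mesh):
    """120 noiseless default-generator samples (fast unit-test dataset)."""
    return generate_dataset(coarse_mesh, default_protocol(), n=120, seed=3)


@pytest.fixture(scope="session")
def e2e(coarse_mesh):
    """Scaled end-to-end study: n=1000, 80/20 split, QDA-PCA and CART banks.

    Returns dict with the dataset, split indices, fitted banks and
    per-held-out-frame FitReports per method.
    """
    seed = 42
    ds = generate_dataset(coarse_mesh, default_protocol(), n=1000, seed=seed)
    train_idx, test_idx = holdout_split(ds.n, 0.2, seed)
    train = Dataset(ds.X[train_idx], ds.Y[train_idx], ds.metadata)
    out = {"mesh": coarse_mesh, "dataset": ds, "train_idx": train_idx,
           "test_idx": test_idx, "banks": {}, "reports": {}}
    for method in ("qda-pca", "cart"):
        res = ElementBank(train, method=method).fit(seed=seed)
        out["banks"][method] = res
        out["reports"][method] = [
            fit_report(reconstruct(res, ds.X[i]), ds.Y[i], 0.5) for i in test_idx
        ]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20230131)
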