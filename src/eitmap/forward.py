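"""Linear FEM forward solver for the 2D conductivity equation.

Solves div(sigma grad u) = 0 with piecewise-linear elements and a gap
(shunt-free Neumann) electrode model: injected current is spread over the
source electrode's boundary edges proportionally to edge length, and the
potential is grounded by the zero-mean constraint.  The resulting stiffness
operator is symmetric positive-semidefinite with the constant vector as
its null space, so discrete reciprocity holds exactly (up to solver
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._errors import SolverError, ValidationError
from .mesh import TorsoMesh
from .protocol import MeasurementProtocol

__all__ = [
    "ConductivityField",
    "MeasurementFrame",
    "ForwardModel",
    "assemble_system",
    "solve_injection",
    "simulate_frame",
    "add_noise",
]


@dataclass
class ConductivityField:
    """Element-wise constant conductivity in S/m, aligned with mesh elements."""

    element_values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.element_values, dtype=float)
        if v.ndim != 1:
            raise ValidationError("conductivity must be a 1-D per-element vector")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValidationError("conductivity values must be finite and > 0")
        self.element_values = v

    @classmethod
    def homogeneous(cls, mesh: TorsoMesh, sigma: float) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, float(sigma)))


@dataclass
class MeasurementFrame:
    """One frame of boundary voltages (volts) under a protocol."""

    values: np.ndarray
    protocol: MeasurementProtocol
    noise_record: Optional[dict] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.protocol.frame_length:
            raise ValidationError("frame length does not match the protocol")
        if not np.all(np.isfinite(v)):
            raise ValidationError("frame contains non-finite voltages")
        self.values = v


def assemble_system(mesh: TorsoMesh, field: ConductivityField) -> sp.csr_matrix:
    """Galerkin stiffness matrix for div(sigma grad u) = 0.

    Symmetric PSD; its null space is spanned by the constant vector
    (row sums are zero).
    """
    sigma = field.element_values
    if len(sigma) != mesh.n_elements:
        raise ValidationError("conductivity field is not aligned with the mesh")
    p = mesh.nodes[mesh.elements]  # (E, 3, 2)
    # Edge vectors opposite each local vertex; grad of hat function i is
    # perpendicular to the opposite edge: grad_i = rot90(e_i) / (2A).
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    area = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    area = np.abs(area)
    g = np.stack([e0, e1, e2], axis=1)  # (E, 3, 2)
    grads = np.stack([-g[..., 1], g[..., 0]], axis=-1) / (2 * area)[:, None, None]
    # local stiffness: sigma * A * grad_i . grad_j
    local = np.einsum("eid,ejd->eij", grads, grads) * (sigma * area)[:, None, None]
    rows = np.repeat(mesh.elements, 3, axis=1).reshape(-1)
    cols = np.tile(mesh.elements, (1, 3)).reshape(-1)
    K = sp.coo_matrix((local.reshape(-1), (rows, cols)), shape=(mesh.n_nodes,) * 2)
    return K.tocsr()


class ForwardModel:
    """Factorized forward operator for one (mesh, conductivity) pair.

    Caches the sparse LU factorization of the grounded system so that all
    injections of a protocol reuse one factorization.
    """

    def __init__(self, mesh: TorsoMesh, field: ConductivityField):
        self.mesh = mesh
        self.field = field
        self.K = assemble_system(mesh, field)
        # Ground node 0 (loads are compatible: they sum to zero), then
        # recenter to the unique zero-mean solution.
        n = mesh.n_nodes
        Kg = self.K[1:, 1:].tocsc()
        try:
            self._lu = spla.splu(Kg)
        except RuntimeError as exc:  # pragma: no cover - disconnected mesh
            raise SolverError(f"grounded stiffness is singular: {exc}") from exc
        self._n = n
        self._Knorm = spla.norm(self.K)
        self._weights = [self._electrode_weights(k) for k in range(len(mesh.electrodes))]

    def _electrode_weights(self, k: int) -> np.ndarray:
        """Length-normalized nodal weight vector of electrode k.

        The same vector distributes injected current over the electrode
        (Neumann load) and averages nodal potentials for measurement;
        using one vector for both is what makes reciprocity exact.
        """
        edges = self.mesh.electrode_edge_nodes(k)
        lengths = self.mesh.edge_lengths(edges)
        total = lengths.sum()
        w = np.zeros(self._n)
        for (a, b), L in zip(edges, lengths):
            w[a] += 0.5 * L / total
            w[b] += 0.5 * L / total
        return w

    def solve_load(self, f: np.ndarray) -> np.ndarray:
        """Solve K u = f with zero-mean grounding; f must sum to zero."""
        u = np.empty(self._n)
        u[0] = 0.0
        u[1:] = self._lu.solve(f[1:])
        resid = np.linalg.norm(self.K @ u - f)
        scale = np.linalg.norm(f)
        if scale > 0 and resid > 1e-10 * max(1.0, np.linalg.norm(u)) * self._Knorm:
            raise SolverError(f"linear solve residual too large: {resid:.3e}")
        return u - u.mean()

    def solve_injection(self, source: int, sink: int, current: float) -> np.ndarray:
        """Nodal potentials (zero mean) for one injection pair."""
        if source == sink:
            raise ValidationError("source and sink electrodes must differ")
        f = current * (self._weights[source] - self._weights[sink])
        return self.solve_load(f)

    def electrode_potential(self, u: np.ndarray, electrode: int) -> float:
        """Length-weighted mean potential over an electrode's edges."""
        return float(self._weights[electrode] @ u)

    def simulate_frame(self, protocol: MeasurementProtocol) -> MeasurementFrame:
        protocol.validate_for(len(self.mesh.electrodes))
        sols = {}
        vals = np.empty(protocol.frame_length)
        for j, (inj, el) in enumerate(protocol.measurements):
            if inj not in sols:
                src, sink, amp = protocol.injection_pairs[inj]
                sols[inj] = self.solve_injection(src, sink, amp)
            vals[j] = self.electrode_potential(sols[inj], el)
        return MeasurementFrame(vals, protocol)


def solve_injection(
    mesh: TorsoMesh, field: ConductivityField, source: int, sink: int, current: float
) -> np.ndarray:
    """One-shot nodal solve; prefer ForwardModel when reusing the mesh/field."""
    return ForwardModel(mesh, field).solve_injection(source, sink, current)


def simulate_frame(
    mesh: TorsoMesh, field: ConductivityField, protocol: MeasurementProtocol
) -> MeasurementFrame:
    """Simulate one measurement frame for a conductivity field."""
    return ForwardModel(mesh, field).simulate_frame(protocol)


def add_noise(frame: MeasurementFrame, snr_db: float, rng) -> MeasurementFrame:
    """Additive white Gaussian noise calibrated to a per-frame SNR in dB.

    The noise variance is set so that 10 log10(mean(x^2) / var) = snr_db.
    ``snr_db = inf`` disables noise and returns the frame unchanged.
    """
    if np.isinf(snr_db):
        return frame
    if not np.isfinite(snr_db):
        raise ValidationError("snr_db must be finite or +inf")
    rng = np.random.default_rng(rng)
    power = float(np.mean(frame.values**2))
    var = power / 10 ** (snr_db / 10)
    noisy = frame.values + rng.normal(0.0, np.sqrt(var), size=frame.values.shape)
    record = {"model": "awgn", "snr_db": float(snr_db), "variance": var}
    return MeasurementFrame(noisy, frame.protocol, noise_record=record)
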