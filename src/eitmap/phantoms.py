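"""Random bladder-like inclusion phantoms and labeled dataset generation.

Each sample embeds one inclusion — a rotated ellipse with an optional
low-order radial Fourier perturbation — in a homogeneous background,
forward-solves the boundary voltages, and labels every mesh element by
whether its centroid lies inside the inclusion.  The ellipse family with
order <= 3 perturbation spans smooth bladder-like blobs with 5-11 degrees
of freedom, which is what makes the voltage frames effectively low-rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._errors import GeneratorError, ValidationError
from .forward import ConductivityField, ForwardModel, MeasurementFrame, add_noise
from .mesh import SuperellipseOutline, TorsoMesh, default_torso_outline
from .protocol import MeasurementProtocol

__all__ = [
    "InclusionShape",
    "LabeledSample",
    "Dataset",
    "default_region",
    "sample_inclusion",
    "labels_from_shape",
    "generate_dataset",
]

#: Default background (soft tissue) and inclusion (urine) conductivities, S/m.
SIGMA_BACKGROUND = 0.2
SIGMA_INCLUSION = 1.0


@dataclass
class InclusionShape:
    """Rotated ellipse with optional radial Fourier perturbation.

    The boundary radius at body-frame polar angle theta is
    ``r_ellipse(theta) * (1 + sum_k c_k cos(k theta) + s_k sin(k theta))``.
    """

    center: np.ndarray
    semi_axes: tuple
    rotation: float = 0.0
    fourier_cos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fourier_sin: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValidationError("semi-axes must be positive")
        self.fourier_cos = np.asarray(self.fourier_cos, dtype=float)
        self.fourier_sin = np.asarray(self.fourier_sin, dtype=float)
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        if np.any(1.0 + self._perturbation(th) <= 0):
            raise ValidationError("radial perturbation makes the boundary radius negative")

    def _perturbation(self, theta: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta)
        for k, c in enumerate(self.fourier_cos, start=1):
            out += c * np.cos(k * theta)
        for k, s in enumerate(self.fourier_sin, start=1):
            out += s * np.sin(k * theta)
        return out

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius at shape-frame angle theta."""
        a, b = self.semi_axes
        r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        return r_ell * (1.0 + self._perturbation(theta))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict point-in-shape test; boundary points count as outside."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        local = pts @ np.array([[c, -s], [s, c]]).T
        rho = np.hypot(local[:, 0], local[:, 1])
        theta = np.arctan2(local[:, 1], local[:, 0])
        return rho < self.radius(theta)

    def boundary_points(self, k: int = 64) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
        r = self.radius(theta)
        local = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return local @ np.array([[c, -s], [s, c]]).T + self.center

    def area(self, k: int = 720) -> float:
        """Polar area integral of the perturbed ellipse."""
        theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
        return float(0.5 * np.mean(self.radius(theta) ** 2) * 2 * np.pi)


@dataclass
class LabeledSample:
    frame: MeasurementFrame
    labels: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.labels)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be binary")
        self.labels = y.astype(np.uint8)


@dataclass
class Dataset:
    """n labeled measurement frames: X (n x m) voltages, Y (n x E) labels."""

    X: np.ndarray
    Y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=np.uint8)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError("X and Y must have the same number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "X.csv", self.X, delimiter=",", fmt="%.17g")
        np.savetxt(d / "Y.csv", self.Y, delimiter=",", fmt="%d")
        (d / "meta.json").write_text(json.dumps(self.metadata, indent=1, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "Dataset":
        d = Path(directory)
        X = np.loadtxt(d / "X.csv", delimiter=",", ndmin=2)
        Y = np.loadtxt(d / "Y.csv", delimiter=",", dtype=np.uint8, ndmin=2)
        meta = json.loads((d / "meta.json").read_text())
        return cls(X, Y, meta)


def default_region(outline: Optional[SuperellipseOutline] = None) -> tuple:
    """Admissible inclusion-center box (xmin, xmax, ymin, ymax).

    The bladder is a midline organ of the lower abdomen that cannot touch
    the body wall, so centers are drawn from a box spanning the central
    ~27% of the half-width and the lower interior in depth.
    """
    if outline is None:
        outline = default_torso_outline()
    a, b = outline.a, outline.b
    return (-0.27 * a, 0.27 * a, -0.65 * b, -0.20 * b)


def sample_inclusion(
    rng,
    region: Optional[tuple] = None,
    size_bounds: tuple = (0.018, 0.038),
    perturbation_order: int = 3,
    perturbation_scale: float = 0.03,
    outline: Optional[SuperellipseOutline] = None,
    wall_margin: float = 0.15,
    max_retries: int = 200,
) -> InclusionShape:
    """Draw one random inclusion entirely inside the torso.

    Center uniform in ``region``, semi-axes uniform in ``size_bounds``,
    rotation uniform in [0, pi), zero-mean Gaussian Fourier coefficients of
    order <= ``perturbation_order``.  Shapes crossing the shrunken outline
    (margin as a fraction of the half-axes) are resampled.
    """
    rng = np.random.default_rng(rng)
    if outline is None:
        outline = default_torso_outline()
    if region is None:
        region = default_region(outline)
    xmin, xmax, ymin, ymax = region
    lo, hi = size_bounds
    shrink_a = outline.a * (1 - wall_margin)
    shrink_b = outline.b * (1 - wall_margin)
    for _ in range(max_retries):
        center = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        axes = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        rot = rng.uniform(0.0, np.pi)
        if perturbation_order > 0 and perturbation_scale > 0:
            fc = rng.normal(0.0, perturbation_scale, perturbation_order)
            fs = rng.normal(0.0, perturbation_scale, perturbation_order)
        else:
            fc = fs = np.zeros(0)
        try:
            shape = InclusionShape(center, axes, rot, fc, fs)
        except ValidationError:
            continue
        bp = shape.boundary_points(64)
        inside = (np.abs(bp[:, 0]) / shrink_a) ** outline.p + (
            np.abs(bp[:, 1]) / shrink_b
        ) ** outline.p
        if np.all(inside <= 1.0):
            return shape
    raise GeneratorError(
        "could not place an inclusion inside the domain; "
        "check region/size bounds against the outline"
    )


def labels_from_shape(mesh: TorsoMesh, shape: InclusionShape) -> np.ndarray:
    """Binary per-element labels: 1 iff the element centroid is strictly inside."""
    return shape.contains(mesh.element_centroids).astype(np.uint8)


def generate_dataset(
    mesh: TorsoMesh,
    protocol: MeasurementProtocol,
    n: int = 5000,
    sigma_background: float = SIGMA_BACKGROUND,
    sigma_inclusion: float = SIGMA_INCLUSION,
    snr_db: float = np.inf,
    seed: int = 0,
    outline: Optional[SuperellipseOutline] = None,
    region: Optional[tuple] = None,
    size_bounds: tuple = (0.018, 0.038),
    perturbation_order: int = 3,
    perturbation_scale: float = 0.03,
) -> Dataset:
    """Simulate the labeled training set D of n (frame, label) pairs.

    Each sample derives its own rng from ``(seed, i)`` so regeneration is
    bit-exact and order-independent.  Noise defaults to off.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    E = mesh.n_elements
    X = np.empty((n, protocol.frame_length))
    Y = np.empty((n, E), dtype=np.uint8)
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        try:
            shape = sample_inclusion(
                rng,
                region=region,
                size_bounds=size_bounds,
                perturbation_order=perturbation_order,
                perturbation_scale=perturbation_scale,
                outline=outline,
            )
            y = labels_from_shape(mesh, shape)
            sigma = np.full(E, sigma_background)
            sigma[y == 1] = sigma_inclusion
            frame = ForwardModel(mesh, ConductivityField(sigma)).simulate_frame(protocol)
            if np.isfinite(snr_db):
                frame = add_noise(frame, snr_db, rng)
        except Exception as exc:
            raise GeneratorError(f"sample {i} failed: {exc}") from exc
        X[i] = frame.values
        Y[i] = y
    meta = {
        "n": n,
        "seed": int(seed),
        "sigma_background": sigma_background,
        "sigma_inclusion": sigma_inclusion,
        "snr_db": None if np.isinf(snr_db) else float(snr_db),
        "protocol": protocol.to_dict(),
        "size_bounds": list(size_bounds),
        "perturbation_order": perturbation_order,
        "perturbation_scale": perturbation_scale,
        "n_elements": E,
    }
    return Dataset(X, Y, meta)
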