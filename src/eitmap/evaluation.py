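"""Reconstruction maps and the fit / image-quality metric suite.

A trained bank turns a measurement frame into a per-element probability
map; thresholding it (0.5 by default) gives the binary reconstruction.
Agreement with the true inclusion pattern is summarized by the standard
confusion-matrix rates, Cohen's kappa, McNemar's chi-square (raw and
continuity-corrected) and the ROC/AUC, and — after rasterizing the FEM
map to an N x N pixel grid — by MSE, MAE, PSNR and a single-window SSIM.

Rates with a zero denominator are reported as NaN sentinels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._errors import ValidationError
from .forward import MeasurementFrame
from .mesh import TorsoMesh

__all__ = [
    "ProbabilityMap",
    "BinaryMap",
    "ConfusionCounts",
    "FitReport",
    "ROCCurve",
    "RasterImage",
    "ImageQualityReport",
    "reconstruct",
    "threshold_map",
    "confusion",
    "fit_measures",
    "cohens_kappa",
    "mcnemar",
    "roc_curve",
    "rasterize",
    "image_quality",
    "fit_report",
]


@dataclass
class ProbabilityMap:
    """Per-element inclusion probabilities for one frame."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        self.values = v


@dataclass
class BinaryMap:
    """Thresholded probability map: 1 iff p >= threshold."""

    values: np.ndarray
    threshold: float

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(np.uint8)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def reconstruct(bank_results, frame) -> ProbabilityMap:
    """Per-element probability map for one measurement frame."""
    if isinstance(frame, MeasurementFrame):
        proto = bank_results.metadata.get("protocol")
        if proto is not None and proto != frame.protocol.to_dict():
            raise ValidationError("frame protocol differs from the bank's training protocol")
        values = frame.values
    else:
        values = np.asarray(frame, dtype=float)
    p = bank_results.predict_proba(values)
    return ProbabilityMap(np.clip(p, 0.0, 1.0), provenance={"method": bank_results.method})


def threshold_map(pmap: ProbabilityMap, t: float = 0.5) -> BinaryMap:
    """Binary map: element classified as inclusion iff p >= t (inclusive)."""
    if not 0.0 <= t <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    return BinaryMap((pmap.values >= t).astype(np.uint8), t)


def confusion(pred, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN with inclusion as the positive case."""
    p = pred.values if isinstance(pred, BinaryMap) else np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError("prediction and truth lengths differ")
    p, t = p.astype(bool), t.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class FitReport:
    """Confusion-matrix fit statistics for one reconstruction."""

    accuracy: float
    sensitivity: float
    specificity: float
    pos_pred_value: float
    neg_pred_value: float
    precision: float
    f1: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float
    kappa: float
    mcnemar_raw: float
    mcnemar_corrected: float
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    def rounded(self, decimals: int = 3) -> dict:
        """Half-up rounding used when rendering report tables."""
        return {k: round_half_up(v, decimals) for k, v in self.to_dict().items()}

    def summary(self) -> str:
        rows = self.rounded()
        width = max(len(k) for k in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows.items())


def round_half_up(x: float, decimals: int = 3) -> float:
    if not np.isfinite(x):
        return x
    scale = 10**decimals
    return float(np.floor(x * scale + 0.5) / scale)


def fit_measures(counts: ConfusionCounts) -> FitReport:
    """Standard confusion-matrix rates (sensitivity = TPR, precision = PPV)."""
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    total = counts.total
    if total <= 0:
        raise ValidationError("empty confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    return FitReport(
        accuracy=_ratio(tp + tn, total),
        sensitivity=sens,
        specificity=spec,
        pos_pred_value=ppv,
        neg_pred_value=_ratio(tn, tn + fn),
        precision=ppv,
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        prevalence=_ratio(tp + fn, total),
        detection_rate=_ratio(tp, total),
        detection_prevalence=_ratio(tp + fp, total),
        balanced_accuracy=(sens + spec) / 2,
        kappa=cohens_kappa(counts),
        mcnemar_raw=mcnemar(counts, corrected=False),
        mcnemar_corrected=mcnemar(counts, corrected=True),
    )


def cohens_kappa(counts: ConfusionCounts) -> float:
    """Chance-corrected agreement between prediction and truth.

    kappa = 2 (TP TN - FN FP) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)],
    algebraically equal to (p_o - p_e) / (1 - p_e).
    """
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if den == 0:
        return float("nan")
    return 2.0 * (tp * tn - fn * fp) / den


def mcnemar(counts: ConfusionCounts, corrected: bool = False) -> float:
    """McNemar chi-square on the discordant counts (FP vs FN).

    Raw form (FP - FN)^2 / (FP + FN); the corrected form applies the
    continuity correction (|FP - FN| - 1)^2 / (FP + FN).  Returns 0 when
    there are no discordant elements.
    """
    fp, fn = counts.FP, counts.FN
    if fp + fn == 0:
        return 0.0
    if corrected:
        return (abs(fp - fn) - 1) ** 2 / (fp + fn)
    return (fp - fn) ** 2 / (fp + fn)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(pmap, truth) -> ROCCurve:
    """ROC over all distinct probability thresholds; AUC by trapezoid.

    Equals the Mann-Whitney pair-counting statistic (ties counted half).
    """
    p = pmap.values if isinstance(pmap, ProbabilityMap) else np.asarray(pmap, dtype=float)
    y = np.asarray(truth).astype(bool)
    if p.shape != y.shape:
        raise ValidationError("probability and truth lengths differ")
    npos, nneg = int(y.sum()), int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValidationError("ROC needs both classes present in truth")
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(ps))[0], len(ps) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(~ys)[distinct]
    tpr = np.r_[0.0, tp / npos]
    fpr = np.r_[0.0, fp / nneg]
    thresholds = np.r_[np.inf, ps[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, fpr, tpr, auc)


def fit_report(pmap, truth, threshold: float = 0.5) -> FitReport:
    """Full FitReport (rates + kappa + McNemar + AUC) for one map."""
    pm = pmap if isinstance(pmap, ProbabilityMap) else ProbabilityMap(pmap)
    counts = confusion(threshold_map(pm, threshold), truth)
    report = fit_measures(counts)
    try:
        report.auc = roc_curve(pm, truth).auc
    except ValidationError:
        report.auc = float("nan")
    return report


# ---------------------------------------------------------------------------
# Raster image metrics


@dataclass
class RasterImage:
    """Square pixel grid over the mesh bounding box (pixels outside = 0)."""

    pixels: np.ndarray
    extent: tuple  # (xmin, xmax, ymin, ymax)

    def __post_init__(self):
        a = np.asarray(self.pixels, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("raster must be square")
        if not np.all(np.isfinite(a)):
            raise ValidationError("raster contains non-finite values")
        self.pixels = a


def rasterize(element_values, mesh: TorsoMesh, N: int = 64) -> RasterImage:
    """Sample a per-element map on an N x N grid of pixel centers.

    Each pixel takes the value of the element containing its center;
    boundary ties go to the lowest element index; pixels outside the
    domain are 0.
    """
    if N < 8:
        raise ValidationError("N must be >= 8")
    v = np.asarray(element_values, dtype=float)
    if len(v) != mesh.n_elements:
        raise ValidationError("value vector is not aligned with the mesh")
    xmin, ymin = mesh.nodes.min(axis=0)
    xmax, ymax = mesh.nodes.max(axis=0)
    xs = xmin + (np.arange(N) + 0.5) / N * (xmax - xmin)
    ys = ymin + (np.arange(N) + 0.5) / N * (ymax - ymin)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    owner = np.full(len(pts), -1, dtype=np.int64)
    tol = 1e-12
    tri = mesh.nodes[mesh.elements]
    for e in range(mesh.n_elements):
        a, b, c = tri[e]
        unassigned = owner < 0
        if not unassigned.any():
            break
        q = pts[unassigned]
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        l1 = ((b[1] - c[1]) * (q[:, 0] - c[0]) + (c[0] - b[0]) * (q[:, 1] - c[1])) / d
        l2 = ((c[1] - a[1]) * (q[:, 0] - c[0]) + (a[0] - c[0]) * (q[:, 1] - c[1])) / d
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -tol) & (l2 >= -tol) & (l3 >= -tol)
        idx = np.nonzero(unassigned)[0][inside]
        owner[idx] = e
    img = np.zeros(len(pts))
    hit = owner >= 0
    img[hit] = v[owner[hit]]
    return RasterImage(img.reshape(N, N), (float(xmin), float(xmax), float(ymin), float(ymax)))


@dataclass
class ImageQualityReport:
    mse: float
    mae: float
    psnr: float
    ssim: float

    def to_dict(self) -> dict:
        return asdict(self)


def image_quality(
    I: RasterImage, K: RasterImage, data_range: Optional[float] = None
) -> ImageQualityReport:
    """MSE, MAE, PSNR and single-window SSIM between truth I and reconstruction K.

    PSNR uses the dynamic range of the ground-truth image (1 for binary
    truth) as the reference maximum; identical images give PSNR = +inf.
    SSIM is the global one-window form with c1 = (0.01 L)^2,
    c2 = (0.03 L)^2 and L = data_range.
    """
    a, b = I.pixels, K.pixels
    if a.shape != b.shape:
        raise ValidationError("rasters must share the same N")
    if data_range is None:
        rng = float(a.max() - a.min())
        data_range = rng if rng > 0 else 1.0
    diff = a - b
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(data_range**2 / mse)
    L = data_range
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mu_i, mu_k = a.mean(), b.mean()
    var_i, var_k = a.var(), b.var()
    cov = float(np.mean((a - mu_i) * (b - mu_k)))
    ssim = ((2 * mu_i * mu_k + c1) * (2 * cov + c2)) / (
        (mu_i**2 + mu_k**2 + c1) * (var_i + var_k + c2)
    )
    return ImageQualityReport(mse=mse, mae=mae, psnr=float(psnr), ssim=float(ssim))
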