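"""Metric suite: thresholding, confusion statistics, ROC, image quality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitmap._errors import ValidationError
from eitmap.evaluation import (
    BinaryMap,
    ConfusionCounts,
    ProbabilityMap,
    RasterImage,
    cohens_kappa,
    confusion,
    fit_measures,
    image_quality,
    mcnemar,
    rasterize,
    roc_curve,
    round_half_up,
    threshold_map,
)

from _oracles import pair_counting_auc

counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500)
)


def test_threshold_boundary_inclusive():
    pmap = ProbabilityMap(np.array([0.2, 0.5, 0.7]))
    assert np.array_equal(threshold_map(pmap, 0.5).values, [0, 1, 1])
    assert threshold_map(pmap, 0.0).values.all()
    with pytest.raises(ValidationError):
        threshold_map(pmap, 1.0 + 1e-9)


def test_confusion_enumeration_hand_case():
    pred = BinaryMap(np.array([1, 1, 0, 0, 1, 0]), 0.5)
    truth = np.array([1, 0, 1, 0, 1, 1])
    c = confusion(pred, truth)
    assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 2, 1)
    same = confusion(BinaryMap(truth, 0.5), truth)
    assert same.FP == same.FN == 0
    flipped = confusion(BinaryMap(1 - truth, 0.5), truth)
    assert flipped.TP == flipped.TN == 0


@settings(max_examples=200, derandomize=True)
@given(counts_strategy)
def test_fit_measures_algebra(quad):
    tp, fp, fn, tn = quad
    c = ConfusionCounts(tp, fp, fn, tn)
    rep = fit_measures(c)
    assert rep.accuracy * c.total == pytest.approx(tp + tn)
    if np.isfinite(rep.balanced_accuracy):
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )
    assert rep.detection_prevalence >= rep.detection_rate - 1e-15
    assert rep.precision == rep.pos_pred_value or (
        np.isnan(rep.precision) and np.isnan(rep.pos_pred_value)
    )


@settings(max_examples=300, derandomize=True)
@given(counts_strategy)
def test_kappa_equals_chance_corrected_form(quad):
    tp, fp, fn, tn = quad
    c = ConfusionCounts(tp, fp, fn, tn)
    k = cohens_kappa(c)
    n = c.total
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe < 1:
        assert k == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


def test_kappa_perfect_agreement():
    assert cohens_kappa(ConfusionCounts(10, 0, 0, 20)) == pytest.approx(1.0)


@pytest.mark.parametrize("quad,corrected,expected", [
    ((36, 0, 2, 1598), False, 2.0),
    ((28, 88, 0, 1439), True, 86.011),
    ((5, 7, 7, 5), False, 0.0),
])
def test_mcnemar_forms(quad, corrected, expected):
    c = ConfusionCounts(*quad)
    assert round_half_up(mcnemar(c, corrected), 3) == pytest.approx(expected)


def test_mcnemar_no_discordance_sentinel():
    assert mcnemar(ConfusionCounts(4, 0, 0, 9), corrected=False) == 0.0


def test_roc_perfect_and_uninformative():
    truth = np.array([1, 1, 0, 0])
    assert roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), truth).auc == pytest.approx(1.0)
    assert roc_curve(np.full(4, 0.5), truth).auc == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))


def test_roc_matches_pair_counting_oracle(rng):
    p = np.array([0.9, 0.8, 0.8, 0.55, 0.4, 0.4, 0.2, 0.05])
    y = np.array([1, 1, 0, 1, 0, 1, 0, 0])
    assert roc_curve(p, y).auc == pytest.approx(pair_counting_auc(p, y), abs=1e-10)
    for _ in range(10):
        p = rng.choice([0.1, 0.3, 0.5, 0.9], size=30)
        y = rng.integers(0, 2, 30)
        if 0 < y.sum() < 30:
            assert roc_curve(p, y).auc == pytest.approx(pair_counting_auc(p, y), abs=1e-10)


def test_roc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    p = rng.uniform(size=200)
    y = (p + rng.normal(scale=0.3, size=200) > 0.5).astype(int)
    assert roc_curve(p, y).auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)


def test_roc_curve_monotone_endpoints(rng):
    p = rng.uniform(size=50)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    curve = roc_curve(p, y)
    assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
    assert curve.fpr[0] == curve.tpr[0] == 0.0
    assert curve.fpr[-1] == curve.tpr[-1] == 1.0


def test_auc_invariant_under_monotone_transform(rng):
    p = rng.uniform(0.01, 0.99, size=100)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    a1 = roc_curve(p, y).auc
    a2 = roc_curve(p**3, y).auc  # strictly monotone transform
    assert a1 == pytest.approx(a2, abs=1e-12)


# -- rasters ----------------------------------------------------------------


def test_rasterize_constant_and_zero_maps(coarse_mesh):
    const = rasterize(np.full(coarse_mesh.n_elements, 0.7), coarse_mesh, 32)
    inside = const.pixels != 0
    assert np.allclose(const.pixels[inside], 0.7)
    assert inside.sum() > 0.5 * 32 * 32
    zero = rasterize(np.zeros(coarse_mesh.n_elements), coarse_mesh, 32)
    assert not zero.pixels.any()


def test_rasterize_mean_stable_under_refinement(coarse_mesh, rng):
    values = rng.uniform(size=coarse_mesh.n_elements)
    r1 = rasterize(values, coarse_mesh, 32)
    r2 = rasterize(values, coarse_mesh, 64)
    m1 = r1.pixels[r1.pixels != 0].mean()
    m2 = r2.pixels[r2.pixels != 0].mean()
    assert m1 == pytest.approx(m2, rel=0.05)


def test_rasterize_validates_inputs(coarse_mesh):
    with pytest.raises(ValidationError):
        rasterize(np.zeros(coarse_mesh.n_elements), coarse_mesh, 4)
    with pytest.raises(ValidationError):
        rasterize(np.zeros(3), coarse_mesh, 16)


# -- image quality ----------------------------------------------------------


def _img(a):
    a = np.asarray(a, dtype=float)
    return RasterImage(a, (0.0, 1.0, 0.0, 1.0))


def test_identical_images_are_perfect():
    rng = np.random.default_rng(1)
    a = rng.uniform(size=(16, 16))
    rep = image_quality(_img(a), _img(a.copy()))
    assert rep.mse == 0.0 and rep.mae == 0.0
    assert rep.ssim == pytest.approx(1.0)
    assert np.isinf(rep.psnr)


def test_binary_differing_pixels_closed_form(rng):
    N, q = 16, 11
    a = rng.integers(0, 2, (N, N)).astype(float)
    b = a.copy()
    flat = b.ravel()
    idx = rng.choice(N * N, size=q, replace=False)
    flat[idx] = 1 - flat[idx]
    rep = image_quality(_img(a), _img(b))
    assert rep.mse == pytest.approx(q / N**2)
    assert rep.mae == pytest.approx(q / N**2)


def test_psnr_closed_form():
    a = np.zeros((10, 10))
    a[0, 0] = 1.0  # dynamic range 1
    b = a + 0.1  # MSE = 0.01
    rep = image_quality(_img(a), _img(b))
    assert rep.psnr == pytest.approx(20.0)


def test_ssim_symmetric_and_bounded(rng):
    a = rng.uniform(size=(12, 12))
    b = rng.uniform(size=(12, 12))
    r1 = image_quality(_img(a), _img(b), data_range=1.0)
    r2 = image_quality(_img(b), _img(a), data_range=1.0)
    assert r1.ssim == pytest.approx(r2.ssim, abs=1e-12)
    assert r1.ssim <= 1.0


def test_psnr_strictly_decreasing_in_mse():
    a = np.zeros((8, 8))
    a[0, 0] = 1.0
    psnrs = [image_quality(_img(a), _img(a + eps)).psnr for eps in (0.01, 0.05, 0.2)]
    assert psnrs[0] > psnrs[1] > psnrs[2]


def test_round_half_up():
    assert round_half_up(0.97368) == 0.974
    assert round_half_up(0.0005, 3) == 0.001
    assert round_half_up(0.2645) == 0.265
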