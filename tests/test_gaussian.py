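"""Gaussian discriminants: estimators, discriminant scores, posteriors."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eitmap._errors import SolverError, ValidationError
from eitmap.classifiers import GaussianDiscriminant


def _gaussian_data(rng, n0=40, n1=30, m=3, shift=1.0):
    X0 = rng.normal(size=(n0, m))
    X1 = rng.normal(size=(n1, m)) + shift
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return X, y


def test_priors_and_divisors_match_stated_estimators(rng):
    X, y = _gaussian_data(rng)
    res = GaussianDiscriminant(y, X, mode="qda").fit()
    n0, n1 = (y == 0).sum(), (y == 1).sum()
    assert np.allclose(res.priors, [n0 / len(y), n1 / len(y)])
    for k in (0, 1):
        d = X[y == k] - X[y == k].mean(axis=0)
        assert np.allclose(res.class_covs[k], d.T @ d / (len(d) - 1))
    d0 = X[y == 0] - X[y == 0].mean(axis=0)
    d1 = X[y == 1] - X[y == 1].mean(axis=0)
    pooled = (d0.T @ d0 + d1.T @ d1) / (len(y) - 2)
    assert np.allclose(res.pooled_cov, pooled)


def test_qda_reduces_to_affine_when_covariances_equal():
    """Identical class deviations make the QDA log-ratio affine in x."""
    base = np.array([[0.0, 0.0], [1.0, 0.2], [0.4, 1.0], [-0.5, -0.8], [0.3, -0.4]])
    X0 = base
    X1 = base + np.array([2.0, -1.0])
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(5, int), np.ones(5, int)]
    res = GaussianDiscriminant(y, X, mode="qda").fit()
    pts = np.array([[0.0, 0.0], [0.5, -0.25], [1.0, -0.5]])  # collinear
    d = res.discriminant_scores(pts)
    diff = d[:, 1] - d[:, 0]
    assert diff[1] - diff[0] == pytest.approx(diff[2] - diff[1], rel=1e-9)


def test_toward_pooled_shrinkage_endpoints(rng):
    X, y = _gaussian_data(rng)
    qda = GaussianDiscriminant(y, X, mode="qda").fit()
    at1 = GaussianDiscriminant(y, X, mode="rda-alpha").fit(alpha=1.0)
    at0 = GaussianDiscriminant(y, X, mode="rda-alpha").fit(alpha=0.0)
    for k in (0, 1):
        assert np.array_equal(at1.covariances[k], qda.class_covs[k])
        assert np.array_equal(at0.covariances[k], qda.pooled_cov)


def test_spherical_shrinkage_at_gamma_zero(rng):
    X, y = _gaussian_data(rng, m=4)
    res = GaussianDiscriminant(y, X, mode="rda").fit(gamma=0.0)
    s2 = np.trace(res.pooled_cov) / 4
    assert np.allclose(res.covariances[0], s2 * np.eye(4))


def test_1d_lda_hand_case():
    """mu0=0, mu1=2, pooled variance 1, equal priors: d1-d0 = 2x-2."""
    a = 1 / np.sqrt(2)
    X = np.array([[-a], [a], [2 - a], [2 + a]])
    y = np.array([0, 0, 1, 1])
    res = GaussianDiscriminant(y, X, mode="lda").fit()
    assert res.pooled_cov[0, 0] == pytest.approx(1.0)
    xs = np.array([[0.0], [1.0], [3.0]])
    d = res.discriminant_scores(xs)
    assert np.allclose(d[:, 1] - d[:, 0], 2 * xs.ravel() - 2, atol=1e-12)
    # the separating plane: equal scores at x = 1
    assert res.posterior(np.array([[1.0]]))[0] == pytest.approx(0.5)


def test_posterior_is_softmax_of_scores(rng):
    """posterior = expit(d1 - d0); a log-9 score gap gives 0.9."""
    X, y = _gaussian_data(rng)
    res = GaussianDiscriminant(y, X, mode="qda").fit()
    d = res.discriminant_scores(X)
    expected = 1.0 / (1.0 + np.exp(-(d[:, 1] - d[:, 0])))
    assert np.allclose(res.posterior(X), expected, atol=1e-12)
    assert 1.0 / (1.0 + np.exp(-np.log(9.0))) == pytest.approx(0.9)


def test_posterior_complement_on_label_swap(rng):
    X, y = _gaussian_data(rng)
    p = GaussianDiscriminant(y, X, mode="qda").fit().posterior(X)
    q = GaussianDiscriminant(1 - y, X, mode="qda").fit().posterior(X)
    assert np.allclose(p + q, 1.0, atol=1e-12)


@pytest.mark.parametrize("mode", ["lda", "qda"])
def test_posterior_equals_bayes_density_ratio(mode):
    """Softmax over discriminant scores = Bayes with Gaussian densities."""
    rng = np.random.default_rng(99)
    for _ in range(50):
        m = rng.integers(1, 5)
        n0, n1 = rng.integers(m + 2, 100, size=2)
        A = rng.normal(size=(m, m))
        X0 = rng.normal(size=(n0, m)) @ A
        X1 = rng.normal(size=(n1, m)) @ (A + 0.3 * rng.normal(size=(m, m))) + rng.normal(size=m)
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        res = GaussianDiscriminant(y, X, mode=mode).fit()
        probe = X[rng.integers(0, len(X), size=10)]
        post = res.posterior(probe)
        dens = []
        for k in (0, 1):
            cov = res.covariances[k]
            dens.append(res.priors[k] * multivariate_normal.pdf(probe, res.means[k], cov))
        bayes = dens[1] / (dens[0] + dens[1])
        assert np.allclose(post, bayes, atol=1e-10)


def test_rda_predictions_continuous_in_gamma(rng):
    X, y = _gaussian_data(rng, m=4)
    probe = X[:5]
    gammas = np.arange(0.2, 0.8, 1e-3)
    prev = None
    model = GaussianDiscriminant(y, X, mode="rda")
    for g in gammas[:50]:
        p = model.fit(gamma=float(g)).posterior(probe)
        if prev is not None:
            assert np.max(np.abs(p - prev)) < 1e-2
        prev = p


def test_rda_gamma_cv_selection_is_deterministic(rng):
    X, y = _gaussian_data(rng, n0=60, n1=50, m=6)
    g1 = GaussianDiscriminant(y, X, mode="rda").fit(seed=3).gamma
    g2 = GaussianDiscriminant(y, X, mode="rda").fit(seed=3).gamma
    assert g1 == g2 and 0.0 <= g1 <= 1.0


def test_parameter_recovery_root_n_rate():
    """Estimation error of means/covariances halves when n quadruples."""
    true_mu = np.array([1.0, -0.5])
    A = np.array([[1.0, 0.3], [0.0, 0.7]])
    true_cov = A @ A.T

    def err(n, rep):
        rng = np.random.default_rng([rep, n])
        X1 = rng.normal(size=(n, 2)) @ A.T + true_mu
        X0 = rng.normal(size=(n, 2)) @ A.T
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        res = GaussianDiscriminant(y, X, mode="qda").fit()
        return (
            np.linalg.norm(res.means[1] - true_mu)
            + np.linalg.norm(res.class_covs[1] - true_cov)
        )

    e_small = np.mean([err(200, r) for r in range(30)])
    e_big = np.mean([err(800, r) for r in range(30)])
    ratio = e_big / e_small
    assert 0.35 <= ratio <= 0.65  # 0.5 +/- 30%


def test_singular_covariance_instructs_regularization():
    X = np.zeros((10, 3))
    X[:, 0] = np.arange(10)
    y = np.array([0] * 5 + [1] * 5)
    with pytest.raises(SolverError, match="gamma|PCA"):
        GaussianDiscriminant(y, X, mode="qda").fit()


def test_class_size_validation():
    X = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(ValidationError):
        GaussianDiscriminant(np.array([0, 0, 0, 0, 1]), X, mode="lda").fit()
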