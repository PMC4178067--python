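"""Null-model fits, score residuals and aggregation against closed forms."""

import numpy as np
import pytest
import statsmodels.api as sm

from mvgmdr import (
    CovariateMatrix,
    PhenotypeSet,
    RunConfig,
    aggregate_scores,
    estimate_scale,
    fit_null,
    null_scores,
    score_residuals,
)
from mvgmdr.errors import GmdrError
from mvgmdr.null_models import NullFit


def _pheno(values, ids=None, kinds=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    ids = ids or [f"T{j+1}" for j in range(values.shape[1])]
    return PhenotypeSet(values, ids, kinds)


def test_gaussian_intercept_only_closed_form():
    # sample mean and unbiased variance are the ML/moment solutions
    fit = fit_null(_pheno([1.0, 2.0, 3.0]), config=RunConfig())
    assert fit.fitted == pytest.approx(np.full((3, 1), 2.0))
    assert fit.scale == pytest.approx(1.0)  # Pearson chi2 / (N - 1) = 2/2
    t = score_residuals(fit, _pheno([1.0, 2.0, 3.0]))
    assert t.ravel() == pytest.approx([-1.0, 0.0, 1.0])


def test_binomial_intercept_only_closed_form():
    y = _pheno([1.0, 1.0, 1.0, 0.0], kinds=["binary"])
    fit = fit_null(y, config=RunConfig(family="binomial"))
    assert fit.fitted == pytest.approx(np.full((4, 1), 0.75))


def test_binomial_standardization_hand_value():
    # (1 - 0.5)/sqrt(0.25) = 1 at unit dispersion
    fit = NullFit(coefficients=np.zeros(1), coefficient_names=["T1:intercept"],
                  fitted=np.full((1, 1), 0.5), scale=1.0,
                  working_correlation=np.eye(1), alpha=None,
                  corstr="independence", family="binomial", link="logit",
                  variance="binomial", converged=True, n_iter=1, n_params=1,
                  trait_ids=["T1"])
    t = score_residuals(fit, _pheno([1.0], kinds=["binary"]))
    assert t.ravel() == pytest.approx([1.0])


def test_gee_exchangeable_matches_per_trait_glm():
    # balanced complete clusters with per-trait intercepts: the GEE solution
    # equals the per-trait GLM (sample means) for any working correlation
    rng = np.random.default_rng(0)
    y = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.5], [0.0, 1.0]])
    Y = _pheno(y)
    gee = fit_null(Y, config=RunConfig(working_correlation="exchangeable"))
    glm = fit_null(Y, config=RunConfig(working_correlation="independence"))
    assert gee.coefficients == pytest.approx(glm.coefficients, abs=1e-8)
    assert glm.coefficients[:2] == pytest.approx(y.mean(axis=0), abs=1e-10)


def test_gee_with_covariates_matches_statsmodels_glm_under_independence():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    y = 1.0 + 0.5 * x + rng.normal(size=100)
    C = CovariateMatrix(x, ["x"])
    fit = fit_null(_pheno(y), C, RunConfig())
    ref = sm.GLM(y, sm.add_constant(x)).fit()
    assert fit.coefficients == pytest.approx(np.asarray(ref.params), abs=1e-8)


def test_estimate_scale_hand_values():
    assert estimate_scale([-1.0, 0.0, 1.0], 1) == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="perfect fit"):
        assert estimate_scale([0.0, 0.0, 0.0], 1) == 0.0
    with pytest.raises(GmdrError):
        estimate_scale([1.0], 1)


def test_estimate_scale_quadratic_homogeneity():
    r = np.array([0.3, -1.2, 0.7, 2.0])
    assert estimate_scale(2 * r, 1) == pytest.approx(4 * estimate_scale(r, 1))


def test_residuals_zero_at_perfect_fit():
    Y = _pheno([2.0, 2.0, 2.0])
    with pytest.warns(UserWarning, match="perfect fit"):
        fit = fit_null(Y, config=RunConfig())
    assert np.all(score_residuals(fit, Y) == 0.0)


def test_aggregate_scores_modes():
    t = np.array([[0.2, -0.5], [1.0, 3.0]])
    assert aggregate_scores(t, "sum") == pytest.approx([-0.3, 4.0])
    assert aggregate_scores(t, "mean") == pytest.approx([-0.15, 2.0])
    one = np.array([[0.7], [-0.2]])
    for mode in ("sum", "mean"):
        assert aggregate_scores(one, mode) == pytest.approx(one.ravel())


def test_univariate_scores_match_least_squares_oracle():
    # hand-rolled oracle: (y - ybar)/sigma_hat with sigma^2 = SS/(n-1)
    rng = np.random.default_rng(7)
    y = rng.normal(2.0, 3.0, size=500)
    _, t, s = null_scores(_pheno(y), config=RunConfig())
    centred = y - y.mean()
    oracle = centred / np.sqrt(np.sum(centred**2) / (len(y) - 1))
    assert s == pytest.approx(oracle, abs=1e-10)
    assert abs(s.sum()) < 1e-8 * len(y)


def test_gee_whitening_recovers_identity_covariance():
    # exchangeable residual correlation 0.4 at n=5000: whitened components
    # should be empirically uncorrelated with unit variance
    rng = np.random.default_rng(42)
    n, rho = 5000, 0.4
    cov = np.array([[1.0, rho], [rho, 1.0]])
    y = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    Y = _pheno(y)
    fit = fit_null(Y, config=RunConfig(working_correlation="exchangeable"))
    assert fit.alpha == pytest.approx(rho, abs=0.05)
    t = score_residuals(fit, Y)
    emp = np.cov(t.T)
    assert emp == pytest.approx(np.eye(2), abs=0.05)


def test_gee_exchangeable_alpha_matches_moment_oracle():
    # moment oracle: mean cross-product of per-trait standardized residuals
    rng = np.random.default_rng(3)
    n, rho = 2000, -0.3
    y = rng.multivariate_normal([1.0, -1.0], [[1, rho], [rho, 1]], size=n)
    fit = fit_null(_pheno(y), config=RunConfig(working_correlation="exchangeable"))
    r = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    assert fit.alpha == pytest.approx(np.mean(r[:, 0] * r[:, 1]), abs=0.02)


def test_binomial_family_requires_binary_traits():
    with pytest.raises(GmdrError, match="binary"):
        fit_null(_pheno([0.1, 0.9, 0.5]), config=RunConfig(family="binomial"))


def test_aggregation_equivalence_for_classification():
    # sum and mean aggregation differ by a positive factor: same signs
    rng = np.random.default_rng(5)
    y = rng.normal(size=(300, 2))
    Y = _pheno(y)
    cfg_sum = RunConfig(aggregation="sum")
    cfg_mean = RunConfig(aggregation="mean")
    _, _, s_sum = null_scores(Y, config=cfg_sum)
    _, _, s_mean = null_scores(Y, config=cfg_mean)
    assert s_sum == pytest.approx(2.0 * s_mean)
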