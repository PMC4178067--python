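"""Null-model fitting and the score residuals that GMDR classifies.

The null model regresses the traits on intercepts and covariates only — the
target gene-gene/gene-environment effects are omitted (their coefficient block
is fixed at zero).  Three estimation routes share one linear predictor and
link:

* **GLM** — maximum likelihood by iteratively reweighted least squares;
* **QLM** — quasi-likelihood: only the link and the mean-variance relation
  ``var = phi * V(mu)`` are specified;
* **GEE** — Liang-Zeger estimating equations over per-individual clusters of
  trait components, with an independence, exchangeable or unstructured
  working correlation estimated by moments alongside Fisher scoring.

Fitting is delegated to :mod:`statsmodels` (``GLM``/``GEE``).  From a fit we
form per-component standardized residuals ``t_ij = (y_ij - mu_ij) /
sqrt(phi * V(mu_ij))``; for GEE fits the per-cluster residual vector is
additionally whitened by the symmetric inverse square root of the fitted
working correlation.  The per-individual aggregate (sum by default, mean
optionally) of these components is the score the dimensionality-reduction
kernel labels cells with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import CovariateMatrix, PhenotypeSet, RunConfig
from .errors import ConvergenceError, GmdrError, StandardizationError

_VAR_FUNCS = {
    "constant": lambda mu: np.ones_like(mu),
    "binomial": lambda mu: mu * (1.0 - mu),
    "mu": lambda mu: mu,
}

_SM_LINKS = {
    "identity": sm.families.links.Identity,
    "logit": sm.families.links.Logit,
    "log": sm.families.links.Log,
}

# statsmodels family implementing each mean-variance relation
_SM_FAMILY_FOR_VARIANCE = {
    "constant": sm.families.Gaussian,
    "binomial": sm.families.Binomial,
    "mu": sm.families.Poisson,
}


@dataclass
class NullFit:
    """A fitted null model (no target effects).

    ``coefficients`` holds the per-trait intercepts followed by per-trait
    covariate effects; ``fitted`` is the n x J matrix of fitted means;
    ``scale`` is the moment (Pearson chi-square / (N - q)) dispersion
    estimate; ``working_correlation`` is the J x J fitted working correlation
    (identity for independence / univariate fits) and ``alpha`` its
    exchangeable parameter where applicable.
    """

    coefficients: np.ndarray
    coefficient_names: list[str]
    fitted: np.ndarray
    scale: float
    working_correlation: np.ndarray
    alpha: float | None
    corstr: str
    family: str
    link: str
    variance: str
    converged: bool
    n_iter: int
    n_params: int
    trait_ids: list[str]

    @property
    def n_traits(self) -> int:
        return self.fitted.shape[1]


def estimate_scale(pearson_residuals, n_params: int) -> float:
    """Moment estimator of the dispersion: Pearson chi-square over ``N - q``.

    Raises a degrees-of-freedom error when the residual count does not exceed
    the number of estimated mean parameters; warns on a perfect fit.
    """
    r = np.asarray(pearson_residuals, dtype=float).ravel()
    q = int(n_params)
    if r.size <= q:
        raise GmdrError(
            f"cannot estimate scale: {r.size} residuals with {q} fitted parameters"
        )
    phi = float(np.sum(r * r) / (r.size - q))
    if phi == 0.0:
        warnings.warn("all Pearson residuals are zero: perfect fit, scale = 0")
    return phi


def _design_block(C: CovariateMatrix, n: int, J: int, trait_ids, covariate_ids):
    """Stacked per-component design: per-trait intercept + per-trait covariates.

    Rows are ordered (sample 0, trait 0), (sample 0, trait 1), ... so that each
    individual forms one contiguous cluster.
    """
    c = C.n_covariates
    q = J * (1 + c)
    X = np.zeros((n * J, q))
    names = []
    for j, tid in enumerate(trait_ids):
        names.append(f"{tid}:intercept")
    for j, tid in enumerate(trait_ids):
        for cid in covariate_ids:
            names.append(f"{tid}:{cid}")
    rows = np.arange(n * J)
    traits = rows % J
    samples = rows // J
    X[rows, traits] = 1.0
    for j in range(J):
        for k in range(c):
            col = J + j * c + k
            sel = traits == j
            X[rows[sel], col] = C.values[samples[sel], k]
    return X, names


def _check_family(Y: PhenotypeSet, config: RunConfig):
    family = config.family
    if family == "binomial":
        bad = [t for t, k in zip(Y.trait_ids, Y.trait_kinds) if k != "binary"]
        if bad:
            raise GmdrError(f"binomial family requires 0/1 traits; non-binary: {bad}")


def _sm_family(link: str, variance: str):
    return _SM_FAMILY_FOR_VARIANCE[variance](link=_SM_LINKS[link]())


def fit_null(Y: PhenotypeSet, C: CovariateMatrix | None = None,
             config: RunConfig | None = None) -> NullFit:
    """Fit the no-target-effect null model and return a :class:`NullFit`.

    With ``working_correlation='independence'`` (or a single trait) the GEE
    solution coincides with the ordinary GLM, which is fitted directly; the
    exchangeable/unstructured routes run Liang-Zeger estimating equations
    over per-individual clusters.
    """
    config = config or RunConfig()
    n, J = Y.n_samples, Y.n_traits
    C = C if C is not None else CovariateMatrix.empty(n)
    if C.n_samples != n:
        raise GmdrError("covariate rows do not match phenotype rows")
    if n < C.n_covariates + 2:
        raise GmdrError("need at least c + 2 samples to fit the null model")
    _check_family(Y, config)
    link = config.resolve_link()
    variance = config.resolve_variance()
    corstr = config.resolve_corstr(J)
    famobj = _sm_family(link, variance)
    q = J * (1 + C.n_covariates)

    if corstr == "independence" or J == 1:
        coefs, fitted, names, n_iter = [], np.empty((n, J)), [], 0
        exog = np.column_stack([np.ones(n), C.values])
        gaussian_identity = link == "identity" and variance == "constant"
        for j, tid in enumerate(Y.trait_ids):
            try:
                if gaussian_identity:
                    # OLS is the exact ML solution and tolerates zero-variance y
                    res = sm.OLS(Y.values[:, j], exog).fit()
                else:
                    res = sm.GLM(Y.values[:, j], exog, family=famobj).fit(
                        maxiter=config.max_iter, tol=config.tol)
            except Exception as exc:  # perfect separation raises inside statsmodels
                raise ConvergenceError(f"GLM fit failed for trait {tid!r}: {exc}") from exc
            if not np.isfinite(res.params).all():
                raise ConvergenceError(f"GLM fit diverged for trait {tid!r}", last_fit=res)
            coefs.append(res.params)
            fitted[:, j] = res.fittedvalues
            n_iter = max(n_iter, getattr(res, "fit_history", {}).get("iteration", 1) or 1)
        # reorder per-trait [intercept, covs] blocks into the shared layout
        coefficients = np.concatenate(
            [np.array([coefs[j][0] for j in range(J)])]
            + [coefs[j][1:] for j in range(J)]
        )
        _, names = _design_block(C, n, J, Y.trait_ids, C.covariate_ids)
        R = np.eye(J)
        alpha = None
        converged = True
    else:
        X, names = _design_block(C, n, J, Y.trait_ids, C.covariate_ids)
        endog = Y.values.ravel()
        groups = np.repeat(np.arange(n), J)
        cov = (sm.cov_struct.Exchangeable() if corstr == "exchangeable"
               else sm.cov_struct.Unstructured())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GEE(endog, X, groups=groups, family=famobj, cov_struct=cov).fit(
                    maxiter=config.max_iter, ctol=config.tol)
        except Exception as exc:
            raise ConvergenceError(f"GEE fit failed: {exc}") from exc
        if not np.isfinite(res.params).all():
            raise ConvergenceError("GEE fit diverged", last_fit=res)
        coefficients = np.asarray(res.params)
        fitted = np.asarray(res.fittedvalues).reshape(n, J)
        if corstr == "exchangeable":
            alpha = float(res.cov_struct.dep_params)
            alpha = float(np.clip(alpha, -1.0 / (J - 1) + 1e-10, 1.0 - 1e-10))
            R = np.full((J, J), alpha)
            np.fill_diagonal(R, 1.0)
        else:
            alpha = None
            R = np.asarray(res.cov_struct.dep_params, dtype=float).copy()
            R = (R + R.T) / 2.0
            np.fill_diagonal(R, 1.0)
        n_iter = len(getattr(res, "fit_history", {}).get("params", [])) or 1
        converged = True

    if variance == "binomial" and ((fitted <= 1e-12) | (fitted >= 1 - 1e-12)).any():
        raise ConvergenceError(
            "fitted probabilities hit 0/1: possible separation in the binomial null fit")

    vfun = _VAR_FUNCS[variance]
    pearson = (Y.values - fitted) / np.sqrt(vfun(fitted))
    scale = estimate_scale(pearson, q)
    return NullFit(
        coefficients=coefficients,
        coefficient_names=names,
        fitted=fitted,
        scale=scale,
        working_correlation=R,
        alpha=alpha,
        corstr=corstr,
        family=config.family,
        link=link,
        variance=variance,
        converged=converged,
        n_iter=int(n_iter),
        n_params=q,
        trait_ids=list(Y.trait_ids),
    )


def _inv_sqrt(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if (w <= 1e-12).any():
        raise StandardizationError("working correlation is not positive definite")
    return (V / np.sqrt(w)) @ V.T


def score_residuals(fit: NullFit, Y: PhenotypeSet) -> np.ndarray:
    """Per-individual, per-trait standardized score residuals (n x J).

    GLM/QLM: ``t_ij = (y_ij - mu_ij) / sqrt(phi * V(mu_ij))``.  GEE fits with
    a non-trivial working correlation additionally whiten each individual's
    residual vector with ``R^{-1/2}`` so the components are exchangeable on
    the working-model scale.  Exactly zero wherever the fit is perfect.
    """
    if not fit.converged:
        raise ConvergenceError("cannot compute residuals from an unconverged fit")
    if Y.values.shape != fit.fitted.shape:
        raise GmdrError("phenotype dimensions do not match the fitted null model")
    vfun = _VAR_FUNCS[fit.variance]
    v = vfun(fit.fitted)
    if (v <= 0).any():
        raise StandardizationError(
            "variance function is zero/negative at a fitted mean; cannot standardize")
    if fit.scale == 0.0:
        return np.zeros_like(Y.values)
    t = (Y.values - fit.fitted) / np.sqrt(fit.scale * v)
    if fit.corstr != "independence" and fit.n_traits > 1:
        t = t @ _inv_sqrt(fit.working_correlation).T
    return t


def aggregate_scores(t: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Aggregate trait-component residuals to one score per individual."""
    t = np.atleast_2d(np.asarray(t, dtype=float))
    if not np.isfinite(t).all():
        raise GmdrError("score matrix contains non-finite values")
    if mode == "sum":
        return t.sum(axis=1)
    if mode == "mean":
        return t.mean(axis=1)
    raise GmdrError(f"unknown aggregation mode {mode!r}")


def null_scores(Y: PhenotypeSet, C: CovariateMatrix | None = None,
                config: RunConfig | None = None):
    """Convenience pipeline: fit the null, standardize, aggregate.

    Returns ``(fit, t, s)`` where ``t`` is the n x J component matrix and
    ``s`` the aggregated per-individual score vector.
    """
    config = config or RunConfig()
    fit = fit_null(Y, C, config)
    t = score_residuals(fit, Y)
    s = aggregate_scores(t, config.aggregation)
    return fit, t, s
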