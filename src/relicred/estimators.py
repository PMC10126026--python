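"""Deterministic reliability coefficients evaluated on covariance matrices.

Every sampler in this package maps posterior covariance (or factor-parameter)
draws through these functions, so they are written to be cheap and strict:
they validate their input once and fail loudly on degenerate matrices.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .data import ItemResponseMatrix

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


class EstimatorError(ValueError):
    """Raised when a coefficient is undefined for the given matrix."""


def _validate_cov(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise EstimatorError(f"covariance matrix must be square, got {sigma.shape}")
    if sigma.shape[0] < 2:
        raise EstimatorError("need at least 2 items")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > _SYM_TOL * scale:
        raise EstimatorError("covariance matrix is not symmetric")
    return 0.5 * (sigma + sigma.T)


def cronbach_alpha(sigma: np.ndarray) -> float:
    """k/(k-1) * (1 - trace / total); <= 1, may be negative."""
    sigma = _validate_cov(sigma)
    k = sigma.shape[0]
    total = sigma.sum()
    if total <= 0:
        raise EstimatorError(f"total variance must be > 0, got {total}")
    return k / (k - 1.0) * (1.0 - np.trace(sigma) / total)


def guttman_lambda2(sigma: np.ndarray) -> float:
    sigma = _validate_cov(sigma)
    k = sigma.shape[0]
    total = sigma.sum()
    if total <= 0:
        raise EstimatorError(f"total variance must be > 0, got {total}")
    off = sigma - np.diag(np.diag(sigma))
    ssq = (off ** 2).sum()
    return (total - np.trace(sigma) + np.sqrt(k / (k - 1.0) * ssq)) / total


def guttman_lambda6(sigma: np.ndarray) -> float:
    """1 - (sum of residual variances of each item on the rest) / total."""
    sigma = _validate_cov(sigma)
    total = sigma.sum()
    if total <= 0:
        raise EstimatorError(f"total variance must be > 0, got {total}")
    try:
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        raise EstimatorError(
            "covariance matrix is singular; lambda6 is undefined (inspect the "
            "data for linearly dependent items rather than regularizing)"
        ) from None
    resid = 1.0 / np.diag(inv)
    return 1.0 - resid.sum() / total


def glb(sigma: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000) -> float:
    """Greatest lower bound to reliability.

    Maximizes the total error variance sum(theta) subject to
    ``sigma - diag(theta)`` positive semidefinite and 0 <= theta_i <=
    sigma_ii; glb = 1 - sum(theta*) / sum(sigma).  The objective is linear
    and the feasible set convex, so the SLSQP local solution is global.
    """
    sigma = _validate_cov(sigma)
    k = sigma.shape[0]
    total = sigma.sum()
    if total <= 0:
        raise EstimatorError(f"total variance must be > 0, got {total}")
    diag = np.diag(sigma).copy()
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin < -_PSD_TOL * max(np.abs(sigma).max(), 1.0):
        raise EstimatorError("covariance matrix is not positive semidefinite")

    # feasible start: shrink every item variance by the smallest eigenvalue
    theta0 = np.clip(np.full(k, max(eigmin, 0.0)), 0.0, diag)

    def neg_sum(theta: np.ndarray) -> float:
        return -theta.sum()

    def neg_sum_jac(theta: np.ndarray) -> np.ndarray:
        return -np.ones_like(theta)

    def eigs(theta: np.ndarray) -> np.ndarray:
        return np.linalg.eigvalsh(sigma - np.diag(theta))

    def eigs_jac(theta: np.ndarray) -> np.ndarray:
        # d lambda_j / d theta_i = -V[i, j]^2
        _, vec = np.linalg.eigh(sigma - np.diag(theta))
        return -(vec ** 2).T

    res = minimize(
        neg_sum,
        theta0,
        jac=neg_sum_jac,
        method="SLSQP",
        bounds=[(0.0, d) for d in diag],
        constraints=[{"type": "ineq", "fun": eigs, "jac": eigs_jac}],
        options={"maxiter": min(max_iter, 1000), "ftol": tol * max(total, 1.0)},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative
        raise EstimatorError(
            f"glb optimizer failed to converge: {res.message} "
            f"(nit={res.nit}, fun={res.fun})"
        )
    value = float(1.0 - (-res.fun) / total)
    return float(np.clip(value, 0.0, 1.0))


def omega_from_params(
    loadings: np.ndarray,
    residual_variances: np.ndarray,
    latent_variance: float = 1.0,
) -> float:
    """General-factor saturation of a single-factor model.

    omega = (sum loadings)^2 * phi / ((sum loadings)^2 * phi + sum psi).
    """
    lam = np.asarray(loadings, dtype=float)
    psi = np.asarray(residual_variances, dtype=float)
    if lam.shape != psi.shape:
        raise EstimatorError("loadings and residual_variances must match in shape")
    if (psi < 0).any():
        raise EstimatorError("residual variances must be >= 0")
    if latent_variance <= 0:
        raise EstimatorError("latent variance must be > 0")
    common = lam.sum() ** 2 * latent_variance
    denom = common + psi.sum()
    if denom == 0:
        raise EstimatorError("degenerate factor model: zero total variance")
    return float(common / denom)


def item_rest_correlation(sigma: np.ndarray, i: int) -> float:
    """Correlation of item i with the sum of the remaining items."""
    sigma = _validate_cov(sigma)
    k = sigma.shape[0]
    if not 0 <= i < k:
        raise EstimatorError(f"item index {i} out of range for k={k}")
    rest = [j for j in range(k) if j != i]
    cov_i_rest = sigma[i, rest].sum()
    var_rest = sigma[np.ix_(rest, rest)].sum()
    var_i = sigma[i, i]
    if var_rest <= 0 or var_i <= 0:
        raise EstimatorError("zero variance of the item or the rest score")
    return float(cov_i_rest / np.sqrt(var_i * var_rest))


def sample_covariance(data: ItemResponseMatrix) -> np.ndarray:
    """Unbiased (n-1 denominator) covariance of the complete rows."""
    complete = data.complete_cases()
    if complete.n < 2:
        raise EstimatorError("need at least 2 complete rows")
    return np.cov(complete.values, rowvar=False, ddof=1)


_CTT_FUNCS = {
    "alpha": cronbach_alpha,
    "lambda2": guttman_lambda2,
    "lambda6": guttman_lambda6,
    "glb": glb,
}


def ctt_coefficient(name: str, sigma: np.ndarray) -> float:
    """Dispatch a classical-test-theory coefficient by name."""
    try:
        fn = _CTT_FUNCS[name]
    except KeyError:
        raise EstimatorError(f"unknown CTT coefficient {name!r}") from None
    return fn(sigma)
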