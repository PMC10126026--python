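"""Conjugate posterior sampling of the item covariance matrix.

The covariance matrix gets an inverse-Wishart prior with scale
``scale_multiplier * I`` and ``df`` degrees of freedom; combined with a
vague normal prior on the item means this yields an inverse-Wishart
posterior with scale ``scale_multiplier * I + C`` (C the centered
cross-product matrix) and ``df + n`` degrees of freedom.  Draws are
independent, but the chain / burn-in / thinning layout is honored anyway so
that convergence diagnostics work identically for every coefficient.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import invwishart

from .chains import CoefficientChains
from .config import CTT_COEFFICIENTS, CttPrior, McmcConfig
from .data import DataError, ItemResponseMatrix
from .estimators import ctt_coefficient


def _chain_rng(seed: int, chain: int, stream: int = 0) -> np.random.Generator:
    """Independent, reproducible generator per (seed, stream, chain)."""
    return np.random.default_rng([seed, stream, chain])


def _posterior_params(
    values: np.ndarray, prior: CttPrior
) -> tuple[int, np.ndarray]:
    """Degrees of freedom and scale matrix of the covariance posterior."""
    n, k = values.shape
    ym = values.mean(axis=0)
    centered = values - ym
    c = centered.T @ centered
    scale = prior.scale_multiplier * np.eye(k) + c
    # vague-mean correction; vanishes as scale_multiplier -> 0
    w = prior.scale_multiplier * n / (prior.scale_multiplier + n)
    scale = scale + w * np.outer(ym - ym, ym - ym)  # means already removed
    df_post = prior.df_for(k) + n
    return df_post, scale


def posterior_cov_draws(
    data: ItemResponseMatrix,
    prior: CttPrior,
    mcmc: McmcConfig,
    seed: int,
    impute: bool = False,
) -> np.ndarray:
    """Posterior covariance draws of shape (chains, kept, k, k).

    With ``impute=False`` the data must be complete (apply listwise deletion
    first).  With ``impute=True`` missing cells are treated as parameters:
    each iteration alternates a covariance draw with conditional-normal
    draws of every missing cell (data augmentation).
    """
    k = data.k
    if data.n < k:
        warnings.warn(
            f"fewer respondents ({data.n}) than items ({k}); the posterior "
            "relies heavily on the prior",
            stacklevel=2,
        )
    if not impute:
        if data.n_missing:
            raise DataError(
                "data contain missing values; listwise-delete first or enable "
                "imputation"
            )
        df_post, scale = _posterior_params(data.values, prior)
        _check_pd(scale)
        out = np.empty((mcmc.chains, mcmc.kept, k, k))
        for c in range(mcmc.chains):
            rng = _chain_rng(seed, c, stream=1)
            draws = invwishart.rvs(
                df=df_post, scale=scale, size=mcmc.iterations, random_state=rng
            ).reshape(mcmc.iterations, k, k)
            out[c] = draws[mcmc.burn_in :: mcmc.thin][: mcmc.kept]
        return out
    return _posterior_cov_draws_impute(data, prior, mcmc, seed)


def _check_pd(scale: np.ndarray) -> None:
    if np.linalg.eigvalsh(scale)[0] <= 0:
        raise DataError("posterior scale matrix is not positive definite")


def _posterior_cov_draws_impute(
    data: ItemResponseMatrix, prior: CttPrior, mcmc: McmcConfig, seed: int
) -> np.ndarray:
    k = data.k
    fully_missing = ~data.mask.any(axis=1)
    if fully_missing.any():
        warnings.warn(
            f"excluding {int(fully_missing.sum())} fully missing row(s)",
            stacklevel=3,
        )
    keep = ~fully_missing
    mask = data.mask[keep]
    col_means = np.nanmean(np.where(mask, data.values[keep], np.nan), axis=0)
    base = np.where(mask, data.values[keep], col_means[None, :])
    base = base - np.nanmean(base, axis=0)  # center once, like the complete path
    miss_rows = np.where(~mask.all(axis=1))[0]

    out = np.empty((mcmc.chains, mcmc.kept, k, k))
    for c in range(mcmc.chains):
        rng = _chain_rng(seed, c, stream=1)
        x = base.copy()
        kept_i = 0
        for it in range(mcmc.iterations):
            df_post, scale = _posterior_params(x, prior)
            sigma = invwishart.rvs(df=df_post, scale=scale, random_state=rng)
            sigma = np.atleast_2d(sigma)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if kept_i < mcmc.kept:
                    out[c, kept_i] = sigma
                    kept_i += 1
            mu = np.zeros(k)
            for r in miss_rows:
                x[r] = impute_missing_step(x[r], mask[r], mu, sigma, rng)
    return out


def impute_missing_step(
    row: np.ndarray,
    observed: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw the missing cells of one row from their conditional normal.

    Given the observed cells and current (mu, sigma), missing cells are
    jointly normal with the usual conditional mean and covariance.  A row
    with no observed cell is rejected (exclude such rows upstream).
    """
    observed = np.asarray(observed, dtype=bool)
    if not observed.any():
        raise DataError("cannot impute a fully missing row")
    out = np.array(row, dtype=float)
    if observed.all():
        return out
    m = ~observed
    s_oo = sigma[np.ix_(observed, observed)]
    s_mo = sigma[np.ix_(m, observed)]
    s_mm = sigma[np.ix_(m, m)]
    solve = np.linalg.solve(s_oo, (out[observed] - mu[observed]))
    cond_mean = mu[m] + s_mo @ solve
    cond_cov = s_mm - s_mo @ np.linalg.solve(s_oo, s_mo.T)
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    out[m] = rng.multivariate_normal(cond_mean, cond_cov, method="eigh")
    return out


def ctt_coefficient_chains(
    cov_draws: np.ndarray,
    which: Iterable[str],
    prior_draws: Optional[Mapping[str, np.ndarray]] = None,
) -> dict[str, CoefficientChains]:
    """Map covariance draws through the requested CTT coefficients."""
    which = tuple(which)
    unknown = [w for w in which if w not in CTT_COEFFICIENTS]
    if unknown:
        raise ValueError(f"not CTT coefficients: {unknown}")
    chains, kept = cov_draws.shape[:2]
    out: dict[str, CoefficientChains] = {}
    for name in which:
        vals = np.empty((chains, kept))
        for c in range(chains):
            for i in range(kept):
                try:
                    vals[c, i] = ctt_coefficient(name, cov_draws[c, i])
                except Exception as exc:
                    raise RuntimeError(
                        f"{name} failed on draw (chain={c}, iter={i}): {exc}"
                    ) from exc
        pd_ = prior_draws.get(name) if prior_draws else None
        out[name] = CoefficientChains(name=name, draws=vals, prior_draws=pd_)
    return out


def prior_coefficient_draws(
    k: int,
    prior: CttPrior,
    n_draws: int,
    seed: int,
    which: Iterable[str] = CTT_COEFFICIENTS,
) -> dict[str, np.ndarray]:
    """Coefficient draws under the prior: sigma ~ IW(scale_multiplier*I, df)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_draws < 1000:
        warnings.warn("fewer than 1000 prior draws; probabilities will be noisy",
                      stacklevel=2)
    df = prior.df_for(k)
    rng = np.random.default_rng([seed, 17])
    sigmas = invwishart.rvs(
        df=df, scale=prior.scale_multiplier * np.eye(k), size=n_draws,
        random_state=rng,
    ).reshape(n_draws, k, k)
    out = {}
    for name in which:
        out[name] = np.array([ctt_coefficient(name, s) for s in sigmas])
    return out
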