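"""Convergence diagnostics and model-adequacy checks for the factor path."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import ItemResponseMatrix
from .estimators import sample_covariance
from .factor import FactorDraws, implied_covariance

#: decision threshold from common practice: chains mixing poorly
RHAT_PROBLEM_THRESHOLD = 1.1


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.  Identical chains give
    sqrt((n-1)/n) < 1; degenerate chains with zero within-chain variance but
    distinct means give +inf with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains of at least 2 draws")
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        if b > 0.0:
            warnings.warn("zero within-chain variance with distinct chain means",
                          stacklevel=2)
            return float("inf")
        return float(np.sqrt((n - 1) / n))
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def rhat_is_problematic(value: float) -> bool:
    return bool(value > RHAT_PROBLEM_THRESHOLD)


def traceplot_data(chains: np.ndarray) -> list[dict]:
    """Per-chain iteration/value series for the kept draws (no transformation)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.size == 0:
        raise ValueError("chains must be a nonempty 2-D array")
    return [
        {"chain": c + 1,
         "iterations": np.arange(1, chains.shape[1] + 1),
         "values": chains[c].copy()}
        for c in range(chains.shape[0])
    ]


@dataclass
class PpcResult:
    """Observed covariance eigenvalues against simulated 95% bands."""

    observed_eigenvalues: np.ndarray  # descending
    band_lower: np.ndarray
    band_upper: np.ndarray
    inside: np.ndarray  # booleans per rank

    def __post_init__(self) -> None:
        if (self.band_lower > self.band_upper).any():
            raise ValueError("band lower bound exceeds upper bound")

    @property
    def all_inside(self) -> bool:
        return bool(self.inside.all())

    def to_records(self) -> list[dict]:
        return [
            {"rank": r + 1,
             "observed": float(self.observed_eigenvalues[r]),
             "lower": float(self.band_lower[r]),
             "upper": float(self.band_upper[r]),
             "inside": bool(self.inside[r])}
            for r in range(self.observed_eigenvalues.size)
        ]


def simulate_eigenvalue_bands(
    implied_covs: np.ndarray,
    n_rows: int,
    seed: int,
    band_mass: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-wise percentile bands of sample-covariance eigenvalues.

    For each supplied model-implied covariance matrix, one n-row normal
    dataset is simulated and the descending eigenvalues of its sample
    covariance recorded; the bands are the rank-wise (1-mass)/2 and
    1-(1-mass)/2 percentiles.
    """
    rng = np.random.default_rng([seed, 4])
    reps, k = implied_covs.shape[0], implied_covs.shape[1]
    eig = np.empty((reps, k))
    for i in range(reps):
        sim = rng.multivariate_normal(
            np.zeros(k), implied_covs[i], size=n_rows, method="eigh"
        )
        vals = np.linalg.eigvalsh(np.cov(sim, rowvar=False, ddof=1))
        eig[i] = vals[::-1]
    tail = (1.0 - band_mass) / 2.0
    lower = np.quantile(eig, tail, axis=0)
    upper = np.quantile(eig, 1.0 - tail, axis=0)
    return lower, upper


def ppc_eigenvalues(
    data: ItemResponseMatrix,
    factor_draws: FactorDraws,
    n_reps: Optional[int] = None,
    seed: int = 0,
) -> PpcResult:
    """Posterior predictive check on the covariance eigenvalue spectrum."""
    sigma = sample_covariance(data)
    observed = np.linalg.eigvalsh(sigma)[::-1]
    lam = factor_draws.pooled_loadings()
    psi = factor_draws.pooled_residuals()
    phi = factor_draws.latent_variance.ravel()
    available = lam.shape[0]
    if n_reps is None:
        n_reps = min(1000, available)
    if n_reps > available:
        raise ValueError(f"n_reps ({n_reps}) exceeds available draws ({available})")
    rng = np.random.default_rng([seed, 5])
    idx = (
        np.arange(available)
        if n_reps == available
        else rng.choice(available, size=n_reps, replace=False)
    )
    implied = np.stack(
        [implied_covariance(lam[i], psi[i], phi[i]) for i in idx]
    )
    n_rows = int(data.complete_rows.sum())
    lower, upper = simulate_eigenvalue_bands(implied, n_rows, seed)
    inside = (observed >= lower) & (observed <= upper)
    return PpcResult(
        observed_eigenvalues=observed, band_lower=lower, band_upper=upper,
        inside=inside,
    )


@dataclass
class FitResult:
    """Posterior fit indices for the single-factor model."""

    brmsea: float
    brmsea_draws: np.ndarray
    p_brmsea_below: float
    bcfi: float
    bcfi_draws: np.ndarray
    p_bcfi_above: float
    btli: float
    btli_draws: np.ndarray
    p_btli_above: float
    blr: float
    effective_params: float
    n_skipped_draws: int = 0

    def to_dict(self) -> dict:
        return {
            "brmsea": self.brmsea,
            "p_brmsea_below_cutoff": self.p_brmsea_below,
            "bcfi": self.bcfi,
            "p_bcfi_above_cutoff": self.p_bcfi_above,
            "btli": self.btli,
            "p_btli_above_cutoff": self.p_btli_above,
            "blr": self.blr,
            "effective_params": self.effective_params,
            "n_skipped_draws": self.n_skipped_draws,
        }


def _gaussian_loglik(x: np.ndarray, sigma: np.ndarray) -> float:
    """Sum over rows of the zero-mean normal log density (may raise)."""
    k = sigma.shape[0]
    sigma = 0.5 * (sigma + sigma.T)
    chol = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sol = np.linalg.solve(chol, x.T)
    quad = (sol**2).sum(axis=0)
    return float(-0.5 * (quad + k * np.log(2 * np.pi) + logdet).sum())


def bayesian_fit_measures(
    data: ItemResponseMatrix,
    factor_draws: FactorDraws,
    rmsea_cutoff: float = 0.08,
    cfi_cutoff: float = 0.90,
    tli_cutoff: float = 0.90,
    seed: int = 0,
) -> FitResult:
    """Bayesian RMSEA / CFI / TLI and the likelihood-ratio statistic.

    Per posterior draw j the deviance against the saturated model is
    D_j = 2 * (loglik(S) - loglik(Sigma_j)) on the listwise-complete,
    centered data.  The effective number of parameters is
    pD = mean(D_j) - D(posterior-mean parameters); the estimated model
    chi-square per draw is D_j - pD with p* - pD degrees of freedom
    (p* = k(k+1)/2).  Incremental indices compare against an independence
    (diagonal-covariance) model whose variance posterior is conjugate.
    """
    complete = data.complete_cases()
    x = complete.values - complete.values.mean(axis=0)
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    pstar = k * (k + 1) / 2.0
    ll_sat = _gaussian_loglik(x, s)

    lam = factor_draws.pooled_loadings()
    psi = factor_draws.pooled_residuals()
    phi = factor_draws.latent_variance.ravel()
    n_draws = lam.shape[0]

    dev = np.empty(n_draws)
    skipped = 0
    good = np.ones(n_draws, dtype=bool)
    for j in range(n_draws):
        sigma_j = implied_covariance(lam[j], psi[j], phi[j])
        try:
            dev[j] = 2.0 * (ll_sat - _gaussian_loglik(x, sigma_j))
        except np.linalg.LinAlgError:
            good[j] = False
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} draw(s) with singular implied "
                      "covariance", stacklevel=2)
    dev = dev[good]

    sigma_pm = implied_covariance(
        lam[good].mean(axis=0), psi[good].mean(axis=0), float(phi[good].mean())
    )
    dev_pm = 2.0 * (ll_sat - _gaussian_loglik(x, sigma_pm))
    pd_eff = float(dev.mean() - dev_pm)

    dchisq = np.maximum(dev - pstar, 0.0)
    df_eff = max(pstar - pd_eff, 1e-8)
    brmsea_draws = np.sqrt(dchisq / (df_eff * n))

    # independence (null) model: conjugate variance posterior per item
    rng = np.random.default_rng([seed, 6])
    c_diag = (x * x).sum(axis=0)
    null_vars = (1e-10 + c_diag)[None, :] / rng.chisquare(1 + n,
                                                          size=(dev.size, k))
    dev0 = np.empty(dev.size)
    for j in range(dev.size):
        dev0[j] = 2.0 * (ll_sat - _gaussian_loglik(x, np.diag(null_vars[j])))
    dev0_pm = 2.0 * (ll_sat - _gaussian_loglik(x, np.diag(null_vars.mean(axis=0))))
    pd0 = float(dev0.mean() - dev0_pm)
    df0_eff = max(pstar - pd0, 1e-8)

    excess = np.maximum(dev - pstar, 0.0)
    excess0 = np.maximum(dev0 - pstar, 0.0)
    bcfi_draws = 1.0 - excess / np.maximum.reduce([excess0, excess,
                                                   np.full_like(excess, 1e-12)])
    ratio0 = (dev0 - pd0) / df0_eff
    ratio1 = (dev - pd_eff) / df_eff
    btli_draws = (ratio0 - ratio1) / np.maximum(ratio0 - 1.0, 1e-12)

    return FitResult(
        brmsea=float(brmsea_draws.mean()),
        brmsea_draws=brmsea_draws,
        p_brmsea_below=float((brmsea_draws < rmsea_cutoff).mean()),
        bcfi=float(bcfi_draws.mean()),
        bcfi_draws=bcfi_draws,
        p_bcfi_above=float((bcfi_draws > cfi_cutoff).mean()),
        btli=float(btli_draws.mean()),
        btli_draws=btli_draws,
        p_btli_above=float((btli_draws > tli_cutoff).mean()),
        blr=float(dev_pm),
        effective_params=pd_eff,
        n_skipped_draws=skipped,
    )
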