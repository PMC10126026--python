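"""Gibbs sampler for the unidimensional factor model behind omega.

The model is x_i = lambda * f_i + e_i with f_i ~ N(0, phi) and
e_i ~ N(0, diag(psi)).  The sampler cycles, in fixed order, through the
full conditionals of the residual variances, the loadings, the factor
scores, and the latent variance.  The factor scores are rescaled to unit
standard deviation after every update, which pins the model's scale: the
loadings absorb sqrt(phi), and omega is computed from loadings and
residual variances alone.  A reflection step flips the sign of all
loadings whenever their mean is negative, so the loading chains are
unimodal even though omega itself is sign-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chains import CoefficientChains
from .config import FactorPrior, McmcConfig
from .data import DataError, ItemResponseMatrix
from .estimators import omega_from_params

_VAR_FLOOR = 1e-12


@dataclass
class FactorDraws:
    """Posterior draws of the single-factor model, organized by chain."""

    loadings: np.ndarray  # (chains, kept, k)
    residual_variances: np.ndarray  # (chains, kept, k)
    latent_variance: np.ndarray  # (chains, kept)
    omega: np.ndarray  # (chains, kept)
    n_floor_warnings: int = 0

    def __post_init__(self) -> None:
        if (self.residual_variances <= 0).any():
            raise ValueError("residual variance draws must be positive")
        if (self.latent_variance <= 0).any():
            raise ValueError("latent variance draws must be positive")
        if ((self.omega < 0) | (self.omega > 1)).any():
            raise ValueError("omega draws must lie in [0, 1]")
        if (self.loadings.sum(axis=2) < -1e-12).any():
            raise ValueError("loading draws violate the sum(lambda) >= 0 convention")

    @property
    def n_chains(self) -> int:
        return self.omega.shape[0]

    @property
    def kept(self) -> int:
        return self.omega.shape[1]

    @property
    def k(self) -> int:
        return self.loadings.shape[2]

    def pooled_loadings(self) -> np.ndarray:
        return self.loadings.reshape(-1, self.k)

    def pooled_residuals(self) -> np.ndarray:
        return self.residual_variances.reshape(-1, self.k)

    def to_long_records(self) -> list[dict]:
        out = []
        for c in range(self.n_chains):
            for i in range(self.kept):
                rec = {"chain": c + 1, "iteration": i + 1}
                for j in range(self.k):
                    out.append({**rec, "parameter": f"loading_{j + 1}",
                                "value": float(self.loadings[c, i, j])})
                    out.append({**rec, "parameter": f"residual_variance_{j + 1}",
                                "value": float(self.residual_variances[c, i, j])})
                out.append({**rec, "parameter": "latent_variance",
                            "value": float(self.latent_variance[c, i])})
                out.append({**rec, "parameter": "omega",
                            "value": float(self.omega[c, i])})
        return out


def _inv_wishart_1d(rng: np.random.Generator, df: float, scale: float) -> float:
    """One-dimensional inverse-Wishart draw: scale / chi-square(df)."""
    return scale / rng.chisquare(df)


def gibbs_factor_sampler(
    data: ItemResponseMatrix,
    prior: FactorPrior,
    mcmc: McmcConfig,
    seed: int,
    impute: bool = False,
) -> FactorDraws:
    """Run the Gibbs sampler; data are column-centered internally.

    With ``impute=False`` the data must be complete.  With ``impute=True``
    missing cells are redrawn every iteration from their conditional normal
    under the current model-implied covariance matrix (data augmentation).
    """
    if not impute and data.n_missing:
        raise DataError(
            "data contain missing values; listwise-delete first or enable "
            "imputation"
        )
    fully_missing = ~data.mask.any(axis=1)
    if fully_missing.any():
        warnings.warn(
            f"excluding {int(fully_missing.sum())} fully missing row(s)",
            stacklevel=2,
        )
    mask = data.mask[~fully_missing]
    vals = data.values[~fully_missing]
    n, k = vals.shape
    col_means = np.nanmean(np.where(mask, vals, np.nan), axis=0)
    x0 = np.where(mask, vals, col_means[None, :])
    x0 = x0 - x0.mean(axis=0)
    miss_rows = np.where(~mask.all(axis=1))[0] if impute else np.array([], dtype=int)

    h0 = prior.loading_scale
    a0, b0 = prior.resid_shape, prior.resid_scale
    l0 = np.full(k, prior.loading_mean)
    r0 = prior.latent_scale_for(k)
    p0 = prior.latent_df_for(k)

    lam_out = np.empty((mcmc.chains, mcmc.kept, k))
    psi_out = np.empty((mcmc.chains, mcmc.kept, k))
    phi_out = np.empty((mcmc.chains, mcmc.kept))
    om_out = np.empty((mcmc.chains, mcmc.kept))
    n_floor = 0

    for c in range(mcmc.chains):
        rng = np.random.default_rng([seed, 2, c])
        x = x0.copy()
        # start from the prior
        psi = 1.0 / rng.gamma(a0, 1.0 / b0, size=k)
        phi = _inv_wishart_1d(rng, p0, r0)
        w = rng.normal(0.0, np.sqrt(phi), size=n)
        w = w / w.std(ddof=1)
        kept_i = 0
        for it in range(mcmc.iterations):
            # residual variances | scores (loadings integrated via ridge form)
            wtw = float(w @ w)
            ak_prec = 1.0 / h0 + wtw
            avar = 1.0 / ak_prec
            ak = avar * (l0 / h0 + x.T @ w)
            bek = b0 + 0.5 * ((x * x).sum(axis=0) - ak * ak / avar + l0 * l0 / h0)
            inv_psi = rng.gamma(n / 2.0 + a0, 1.0 / bek, size=k)
            psi = 1.0 / np.maximum(inv_psi, _VAR_FLOOR)
            if (inv_psi < _VAR_FLOOR).any():
                n_floor += 1
            # loadings | scores, residual variances
            lam = rng.normal(ak * np.sqrt(phi), np.sqrt(psi * avar))
            if lam.mean() < 0:
                lam = -lam
            # factor scores | loadings, residual variances, latent variance
            prec = 1.0 / phi + float((lam * lam / psi).sum())
            v = 1.0 / prec
            m = v * (x @ (lam / psi))
            w = rng.normal(m, np.sqrt(v))
            w = w / w.std(ddof=1)
            # latent variance | scores
            phi = _inv_wishart_1d(rng, n + p0, float(w @ w) + r0)
            if phi < _VAR_FLOOR:
                phi = _VAR_FLOOR
                n_floor += 1
            if impute and miss_rows.size:
                cc = phi * np.outer(lam, lam) + np.diag(psi)
                x = _impute_columns(x, mask, cc, rng)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if kept_i < mcmc.kept:
                    lam_out[c, kept_i] = lam
                    psi_out[c, kept_i] = psi
                    phi_out[c, kept_i] = phi
                    om_out[c, kept_i] = omega_from_params(lam, psi, 1.0)
                    kept_i += 1
    if n_floor:
        warnings.warn(
            f"{n_floor} variance draw(s) hit the numerical floor", stacklevel=2
        )
    return FactorDraws(
        loadings=lam_out,
        residual_variances=psi_out,
        latent_variance=phi_out,
        omega=om_out,
        n_floor_warnings=n_floor,
    )


def _impute_columns(
    x: np.ndarray, mask: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Redraw missing cells column-by-column given all other columns."""
    k = x.shape[1]
    for j in range(k):
        rows = np.where(~mask[:, j])[0]
        if rows.size == 0:
            continue
        others = [c for c in range(k) if c != j]
        s_oo = sigma[np.ix_(others, others)]
        s_jo = sigma[j, others]
        beta = np.linalg.solve(s_oo, s_jo)
        cond_var = float(sigma[j, j] - s_jo @ beta)
        cond_var = max(cond_var, _VAR_FLOOR)
        mu = x[np.ix_(rows, others)] @ beta
        x[rows, j] = rng.normal(mu, np.sqrt(cond_var))
    return x


def omega_chain(draws: FactorDraws) -> CoefficientChains:
    """Omega evaluated per stored draw (the sampler already computed it)."""
    return CoefficientChains(name="omega", draws=draws.omega.copy())


def prior_omega_draws(
    k: int, prior: FactorPrior, n_draws: int, seed: int
) -> np.ndarray:
    """Draws of omega with factor-model parameters drawn from the prior.

    The loadings prior is normal with variance ``loading_scale * psi_i``,
    conditional on the item's residual variance, matching the sampler's
    conditional structure; omega is computed in the unit-latent-variance
    metric.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng([seed, 3])
    inv_psi = rng.gamma(prior.resid_shape, 1.0 / prior.resid_scale,
                        size=(n_draws, k))
    psi = 1.0 / inv_psi
    lam = rng.normal(prior.loading_mean, np.sqrt(psi * prior.loading_scale))
    common = lam.sum(axis=1) ** 2
    return common / (common + psi.sum(axis=1))


def implied_covariance(
    loadings: np.ndarray, residual_variances: np.ndarray, latent_variance: float
) -> np.ndarray:
    """Model-implied covariance: phi * lambda lambda' + diag(psi)."""
    lam = np.asarray(loadings, dtype=float)
    psi = np.asarray(residual_variances, dtype=float)
    return latent_variance * np.outer(lam, lam) + np.diag(psi)


def standardized_loadings(draws: FactorDraws, estimate: str = "mean") -> np.ndarray:
    """Posterior summary of lambda_i sqrt(phi) / sqrt(phi lambda_i^2 + psi_i)."""
    if estimate not in ("mean", "median"):
        raise ValueError("estimate must be 'mean' or 'median'")
    lam = draws.pooled_loadings()
    psi = draws.pooled_residuals()
    phi = draws.latent_variance.reshape(-1, 1)
    std = lam * np.sqrt(phi) / np.sqrt(phi * lam**2 + psi)
    return std.mean(axis=0) if estimate == "mean" else np.median(std, axis=0)
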