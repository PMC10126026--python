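"""Deterministic generators for synthetic item-response data.

All generators produce continuous multivariate-normal responses; an
optional discretization rounds to a 0-to-(levels-1) Likert grid for
smoke tests shaped like real questionnaire data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import DataError, ItemResponseMatrix
from .estimators import omega_from_params


class GeneratorError(ValueError):
    """Raised for infeasible generator specifications."""


def loadings_for_target_omega(k: int, target_omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Equal loadings and unit-variance residuals hitting a target omega.

    Solves (k * lam)^2 / ((k * lam)^2 + k * psi) = omega with psi = 1 - lam^2,
    giving lam = sqrt(omega / (k * (1 - omega) + omega)).
    """
    if not 0.0 < target_omega < 1.0:
        raise GeneratorError(f"target omega must lie in (0, 1), got {target_omega}")
    lam = np.sqrt(target_omega / (k * (1.0 - target_omega) + target_omega))
    loadings = np.full(k, lam)
    resid = 1.0 - loadings**2
    assert abs(omega_from_params(loadings, resid, 1.0) - target_omega) < 1e-12
    return loadings, resid


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification for a unidimensional factor-model dataset.

    Exactly one of ``loadings`` / ``target_omega`` must be given; with
    ``target_omega``, equal loadings with unit item variances are derived so
    the population omega matches the target exactly.
    """

    n: int
    k: int
    loadings: Optional[tuple[float, ...]] = None
    target_omega: Optional[float] = None
    residual_variances: Optional[tuple[float, ...]] = None
    latent_variance: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.loadings is None) == (self.target_omega is None):
            raise GeneratorError("give exactly one of loadings / target_omega")
        if self.n < 2 or self.k < 2:
            raise GeneratorError("need n >= 2 and k >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise GeneratorError("missing_rate must lie in [0, 1)")
        if self.latent_variance <= 0:
            raise GeneratorError("latent_variance must be > 0")

    def resolve(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(loadings, residual_variances, latent_variance) as arrays."""
        if self.target_omega is not None:
            lam, psi = loadings_for_target_omega(self.k, self.target_omega)
            return lam, psi, self.latent_variance
        lam = np.asarray(self.loadings, dtype=float)
        if lam.size != self.k:
            raise GeneratorError("loadings length must equal k")
        if self.residual_variances is not None:
            psi = np.asarray(self.residual_variances, dtype=float)
            if psi.size != self.k:
                raise GeneratorError("residual_variances length must equal k")
        else:
            psi = np.maximum(1.0 - self.latent_variance * lam**2, 1e-8)
        if (psi <= 0).any():
            raise GeneratorError("residual variances must be positive")
        return lam, psi, self.latent_variance

    def population_covariance(self) -> np.ndarray:
        lam, psi, phi = self.resolve()
        return phi * np.outer(lam, lam) + np.diag(psi)


def make_unidimensional(spec: GeneratorSpec) -> ItemResponseMatrix:
    """Draw rows from x = lambda * f + e under the resolved specification."""
    lam, psi, phi = spec.resolve()
    rng = np.random.default_rng([spec.seed, 10])
    f = rng.normal(0.0, np.sqrt(phi), size=spec.n)
    e = rng.normal(0.0, np.sqrt(psi), size=(spec.n, spec.k))
    values = np.outer(f, lam) + e
    data = ItemResponseMatrix.from_values(values)
    if spec.missing_rate > 0:
        data = inject_missing(data, spec.missing_rate, seed=spec.seed)
    return data


def make_from_covariance(
    sigma: np.ndarray, n: int, seed: int = 0,
    item_names: Optional[Sequence[str]] = None,
) -> ItemResponseMatrix:
    """Zero-mean multivariate-normal rows with the given covariance."""
    sigma = np.asarray(sigma, dtype=float)
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin < -1e-8 * max(np.abs(sigma).max(), 1.0):
        raise GeneratorError("sigma must be positive semidefinite")
    rng = np.random.default_rng([seed, 11])
    values = rng.multivariate_normal(np.zeros(sigma.shape[0]), sigma, size=n,
                                     method="eigh")
    return ItemResponseMatrix.from_values(values, item_names=item_names)


def two_factor_covariance(
    k_per_block: int, between_corr: float, loading: float = 0.7
) -> np.ndarray:
    """Population covariance of two equally loaded blocks.

    Items load ``loading`` on their block factor; the block factors
    correlate ``between_corr``; residuals top items up to unit variance.
    """
    if not 0.0 <= between_corr < 1.0:
        raise GeneratorError("between_corr must lie in [0, 1)")
    k = 2 * k_per_block
    lam = np.zeros((k, 2))
    lam[:k_per_block, 0] = loading
    lam[k_per_block:, 1] = loading
    phi = np.array([[1.0, between_corr], [between_corr, 1.0]])
    sigma = lam @ phi @ lam.T
    np.fill_diagonal(sigma, 1.0)
    return sigma


def make_two_factor(
    n: int, k_per_block: int, between_corr: float, seed: int = 0,
    loading: float = 0.7,
) -> ItemResponseMatrix:
    """Two-block data whose second eigenvalue exceeds the one-factor value."""
    sigma = two_factor_covariance(k_per_block, between_corr, loading)
    return make_from_covariance(sigma, n, seed=seed)


def inject_missing(
    data: ItemResponseMatrix, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> ItemResponseMatrix:
    """Mask cells completely at random; no row is ever left fully missing."""
    if mechanism != "MCAR":
        raise GeneratorError(f"unsupported missingness mechanism {mechanism!r}")
    if not 0.0 <= rate < 1.0:
        raise GeneratorError("rate must lie in [0, 1)")
    if rate == 0.0:
        return data
    rng = np.random.default_rng([seed, 12])
    mask = data.mask.copy()
    for i in range(data.n):
        while True:
            drop = rng.random(data.k) < rate
            new_row = data.mask[i] & ~drop
            if new_row.any():
                mask[i] = new_row
                break
    values = np.where(mask, data.values, np.nan)
    return ItemResponseMatrix(values=values, mask=mask, item_names=data.item_names)


def discretize(data: ItemResponseMatrix, levels: int = 5) -> ItemResponseMatrix:
    """Round standardized scores onto a 0..levels-1 grid (Likert-shaped)."""
    if levels < 2:
        raise GeneratorError("levels must be >= 2")
    v = data.values.copy()
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(v, axis=0)
        sd[sd == 0] = 1.0
        z = (v - np.nanmean(v, axis=0)) / sd
        scaled = (z + 2.5) / 5.0 * (levels - 1)
        v = np.clip(np.round(scaled), 0, levels - 1)
    values = np.where(data.mask, v, np.nan)
    return ItemResponseMatrix(values=values, mask=data.mask.copy(),
                              item_names=data.item_names)
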