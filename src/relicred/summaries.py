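"""Posterior summaries: point estimates, HPD intervals, interval
probabilities, distance measures between posteriors, and plot-ready
densities."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde


@dataclass(frozen=True)
class HpdInterval:
    """Shortest interval containing ``mass`` of the draws."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("HPD lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def point_estimate(draws: np.ndarray, method: str = "mean") -> float:
    """Mean or median of the pooled draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("empty draw array")
    if method == "mean":
        return float(draws.mean())
    if method == "median":
        return float(np.median(draws))
    raise ValueError(f"method must be 'mean' or 'median', got {method!r}")


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> HpdInterval:
    """Shortest-window HPD interval from sorted draws.

    Among all windows of ceil(mass * N) consecutive sorted draws the one of
    minimal width is returned; ties break toward the lowest window.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must lie in (0, 1], got {mass}")
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n == 0:
        raise ValueError("empty draw array")
    if n < 100:
        warnings.warn("fewer than 100 draws; the HPD interval will be noisy",
                      stacklevel=2)
    m = min(n, math.ceil(mass * n))
    widths = draws[m - 1 :] - draws[: n - m + 1]
    j = int(np.argmin(widths))
    return HpdInterval(lower=float(draws[j]), upper=float(draws[j + m - 1]),
                       mass=mass)


def central_interval(draws: np.ndarray, mass: float = 0.95) -> HpdInterval:
    """Equal-tailed credible interval (escape hatch from the HPD default)."""
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must lie in (0, 1], got {mass}")
    draws = np.asarray(draws, dtype=float).ravel()
    tail = (1.0 - mass) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return HpdInterval(lower=float(lo), upper=float(hi), mass=mass)


def prob_in_interval(draws: np.ndarray, lo: float, hi: float) -> float:
    """Fraction of draws strictly inside (lo, hi)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    draws = np.asarray(draws, dtype=float).ravel()
    return float(((draws > lo) & (draws < hi)).mean())


_KDE_GRID = 512


def _shared_grid(p: np.ndarray, q: np.ndarray, grid_size: int = _KDE_GRID
                 ) -> np.ndarray:
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    return np.linspace(lo - 0.05 * span, hi + 0.05 * span, grid_size)


def _kde_on_grid(draws: np.ndarray, grid: np.ndarray) -> np.ndarray:
    dens = gaussian_kde(draws, bw_method="silverman")(grid)
    area = np.trapezoid(dens, grid)
    return dens / area


def kl_divergence_samples(p_draws: np.ndarray, q_draws: np.ndarray) -> float:
    """Discretized KL(p || q) from kernel-density estimates on a shared grid.

    Densities use a Gaussian kernel with Silverman bandwidth on a 512-point
    grid spanning both samples; q is floored at 1e-12 before the log ratio.
    """
    p = np.asarray(p_draws, dtype=float).ravel()
    q = np.asarray(q_draws, dtype=float).ravel()
    if p.size == 0 or q.size == 0:
        raise ValueError("empty draw array")
    grid = _shared_grid(p, q)
    dp = _kde_on_grid(p, grid)
    dq = np.maximum(_kde_on_grid(q, grid), 1e-12)
    step = grid[1] - grid[0]
    mask = dp > 1e-12  # contributions below this are numerically irrelevant
    kl = float(np.sum(dp[mask] * np.log(dp[mask] / dq[mask])) * step)
    return max(kl, 0.0)


def ks_distance_samples(p_draws: np.ndarray, q_draws: np.ndarray) -> float:
    """Maximum absolute difference between the two empirical CDFs."""
    p = np.sort(np.asarray(p_draws, dtype=float).ravel())
    q = np.sort(np.asarray(q_draws, dtype=float).ravel())
    if p.size == 0 or q.size == 0:
        raise ValueError("empty draw array")
    both = np.concatenate([p, q])
    cdf_p = np.searchsorted(p, both, side="right") / p.size
    cdf_q = np.searchsorted(q, both, side="right") / q.size
    return float(np.abs(cdf_p - cdf_q).max())


def density_for_plot(
    draws: np.ndarray, grid_size: int = _KDE_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density on a grid extending 3 bandwidths past the sample range."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("empty draw array")
    kde = gaussian_kde(draws, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(draws.min() - 3 * h, draws.max() + 3 * h, grid_size)
    dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens
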