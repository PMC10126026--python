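"""Container for per-coefficient MCMC draws."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class CoefficientChains:
    """Posterior draws of one reliability coefficient, organized by chain.

    ``draws`` has shape (chains, kept iterations); ``prior_draws`` is an
    optional flat array of draws from the matching prior.
    """

    name: str
    draws: np.ndarray
    prior_draws: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2:
            raise ValueError("draws must have shape (chains, kept)")
        if not np.isfinite(self.draws).all():
            raise ValueError(f"non-finite draw in {self.name} chain")
        if self.prior_draws is not None:
            self.prior_draws = np.asarray(self.prior_draws, dtype=float).ravel()

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def kept(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All kept draws from all chains, flattened."""
        return self.draws.ravel()

    def to_long_records(self) -> list[dict]:
        """Long-format export: one record per (chain, iteration)."""
        out = []
        for c in range(self.n_chains):
            for i in range(self.kept):
                out.append(
                    {"coefficient": self.name, "chain": c + 1,
                     "iteration": i + 1, "value": float(self.draws[c, i])}
                )
        return out
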