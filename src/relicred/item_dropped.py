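"""If-item-dropped analysis: rerun the posterior on every (k-1)-item subset."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chains import CoefficientChains
from .config import AnalysisConfig
from .ctt import ctt_coefficient_chains, posterior_cov_draws
from .data import DataError, ItemResponseMatrix
from .estimators import item_rest_correlation
from .factor import gibbs_factor_sampler, omega_chain
from .summaries import kl_divergence_samples, ks_distance_samples, point_estimate

ORDER_METRICS = ("mean", "kl", "ks")


@dataclass
class ItemDroppedResult:
    """Per-item posteriors when that item is removed, plus an ordering.

    ``order`` lists item indices by decreasing divergence from the
    full-model posterior under the chosen metric.
    """

    coefficient: str
    metric: str
    item_names: tuple[str, ...]
    full_chains: CoefficientChains
    full_mean: float
    dropped_chains: dict[str, CoefficientChains]
    dropped_means: dict[str, float]
    divergences: dict[str, float]
    order: tuple[str, ...]
    item_rest_correlations: dict[str, float] = field(default_factory=dict)


def _coefficient_chains_for(
    data: ItemResponseMatrix, config: AnalysisConfig, coefficient: str
) -> CoefficientChains:
    """Posterior chains for one coefficient on one dataset."""
    impute = config.missing_strategy == "bayes_impute" and data.n_missing > 0
    working = data if impute else (data.complete_cases() if data.n_missing else data)
    if coefficient == "omega":
        draws = gibbs_factor_sampler(
            working, config.factor_prior, config.mcmc, config.seed, impute=impute
        )
        return omega_chain(draws)
    cov = posterior_cov_draws(
        working, config.ctt_prior, config.mcmc, config.seed, impute=impute
    )
    return ctt_coefficient_chains(cov, [coefficient])[coefficient]


def if_item_dropped(
    data: ItemResponseMatrix,
    config: AnalysisConfig,
    coefficient: str,
    metric: str = "kl",
) -> ItemDroppedResult:
    """Recompute the posterior of ``coefficient`` with each item dropped.

    Each subset is re-sampled with the same MCMC settings and seed policy as
    the full model so that the posteriors are comparable.
    """
    if data.k < 3:
        raise DataError("if-item-dropped requires at least 3 items")
    if metric not in ORDER_METRICS:
        raise ValueError(f"metric must be one of {ORDER_METRICS}, got {metric!r}")

    full = _coefficient_chains_for(data, config, coefficient)
    full_pooled = full.pooled()
    full_mean = point_estimate(full_pooled, config.point_estimate)

    dropped_chains: dict[str, CoefficientChains] = {}
    dropped_means: dict[str, float] = {}
    divergences: dict[str, float] = {}
    for idx, name in enumerate(data.item_names):
        sub = data.drop_item(idx)
        ch = _coefficient_chains_for(sub, config, coefficient)
        pooled = ch.pooled()
        dropped_chains[name] = ch
        dropped_means[name] = point_estimate(pooled, config.point_estimate)
        if metric == "mean":
            divergences[name] = abs(dropped_means[name] - full_mean)
        elif metric == "kl":
            divergences[name] = kl_divergence_samples(pooled, full_pooled)
        else:
            divergences[name] = ks_distance_samples(pooled, full_pooled)

    order = tuple(sorted(divergences, key=divergences.get, reverse=True))

    # item-rest correlations: posterior mean over covariance draws
    impute = config.missing_strategy == "bayes_impute" and data.n_missing > 0
    working = data if impute else (data.complete_cases() if data.n_missing else data)
    cov = posterior_cov_draws(
        working, config.ctt_prior, config.mcmc, config.seed, impute=impute
    )
    flat = cov.reshape(-1, data.k, data.k)
    ircs = {
        name: float(np.mean([item_rest_correlation(s, j) for s in flat]))
        for j, name in enumerate(data.item_names)
    }

    return ItemDroppedResult(
        coefficient=coefficient,
        metric=metric,
        item_names=data.item_names,
        full_chains=full,
        full_mean=full_mean,
        dropped_chains=dropped_chains,
        dropped_means=dropped_means,
        divergences=divergences,
        order=order,
        item_rest_correlations=ircs,
    )
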