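"""Top-level orchestration: run a full analysis and write reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .chains import CoefficientChains
from .config import AnalysisConfig
from .ctt import ctt_coefficient_chains, posterior_cov_draws, prior_coefficient_draws
from .data import ItemResponseMatrix
from .diagnostics import (FitResult, PpcResult, bayesian_fit_measures,
                          ppc_eigenvalues, rhat, rhat_is_problematic)
from .estimators import cronbach_alpha, sample_covariance
from .factor import (FactorDraws, gibbs_factor_sampler, omega_chain,
                     prior_omega_draws, standardized_loadings)
from .item_dropped import ItemDroppedResult, if_item_dropped
from .summaries import hpd_interval, point_estimate, prob_in_interval

#: cap on prior draws mapped through the optimization-based glb
_CTT_PRIOR_DRAW_CAP = 2000


@dataclass
class SummaryRow:
    coefficient: str
    estimate: float
    hpd_lower: float
    hpd_upper: float
    rhat: float
    rhat_problematic: bool
    prior_prob: Optional[float] = None
    posterior_prob: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "coefficient": self.coefficient,
            "estimate": self.estimate,
            "hpd_lower": self.hpd_lower,
            "hpd_upper": self.hpd_upper,
            "rhat": self.rhat,
            "rhat_problematic": self.rhat_problematic,
        }
        if self.prior_prob is not None:
            d["prior_prob"] = self.prior_prob
        if self.posterior_prob is not None:
            d["posterior_prob"] = self.posterior_prob
        return d


@dataclass
class AnalysisResult:
    """Everything a run produced, with the configuration echoed."""

    config: AnalysisConfig
    table: list[SummaryRow]
    chains: dict[str, CoefficientChains]
    factor_draws: Optional[FactorDraws] = None
    ppc: Optional[PpcResult] = None
    fit: Optional[FitResult] = None
    std_loadings: Optional[np.ndarray] = None
    item_dropped: dict[str, ItemDroppedResult] = field(default_factory=dict)
    n_rows_used: int = 0
    item_names: tuple[str, ...] = ()

    def row(self, coefficient: str) -> SummaryRow:
        for r in self.table:
            if r.coefficient == coefficient:
                return r
        raise KeyError(f"no summary row for {coefficient!r}")


def run_analysis(data: ItemResponseMatrix, config: AnalysisConfig) -> AnalysisResult:
    """Execute the requested coefficients plus any side outputs.

    Deterministic given ``config.seed``; with zero missing cells the
    listwise and imputation strategies take the identical code path.
    """
    impute = config.missing_strategy == "bayes_impute" and data.n_missing > 0
    working = data if impute else (data.complete_cases() if data.n_missing else data)

    chains: dict[str, CoefficientChains] = {}
    prior_draws: dict[str, np.ndarray] = {}
    factor_draws: Optional[FactorDraws] = None

    ctt_names = config.ctt_coefficients
    if ctt_names:
        cov = posterior_cov_draws(
            working, config.ctt_prior, config.mcmc, config.seed, impute=impute
        )
        if config.prob_interval is not None:
            n_prior = min(config.n_prior_draws, _CTT_PRIOR_DRAW_CAP)
            prior_draws.update(
                prior_coefficient_draws(
                    working.k, config.ctt_prior, n_prior, config.seed,
                    which=ctt_names,
                )
            )
        chains.update(ctt_coefficient_chains(cov, ctt_names, prior_draws))

    if config.wants_omega:
        factor_draws = gibbs_factor_sampler(
            working, config.factor_prior, config.mcmc, config.seed, impute=impute
        )
        om = omega_chain(factor_draws)
        if config.prob_interval is not None:
            prior_draws["omega"] = prior_omega_draws(
                working.k, config.factor_prior, config.n_prior_draws, config.seed
            )
            om.prior_draws = prior_draws["omega"]
        chains["omega"] = om

    table: list[SummaryRow] = []
    for name in config.coefficients:
        ch = chains[name]
        pooled = ch.pooled()
        est = point_estimate(pooled, config.point_estimate)
        hpd = hpd_interval(pooled, config.ci_mass)
        r = rhat(ch.draws) if ch.n_chains >= 2 else float("nan")
        prior_p = post_p = None
        if config.prob_interval is not None:
            lo, hi = config.prob_interval
            post_p = prob_in_interval(pooled, lo, hi)
            if ch.prior_draws is not None:
                prior_p = prob_in_interval(ch.prior_draws, lo, hi)
        table.append(
            SummaryRow(
                coefficient=name,
                estimate=est,
                hpd_lower=hpd.lower,
                hpd_upper=hpd.upper,
                rhat=r,
                rhat_problematic=rhat_is_problematic(r) if np.isfinite(r) else False,
                prior_prob=prior_p,
                posterior_prob=post_p,
            )
        )

    result = AnalysisResult(
        config=config,
        table=table,
        chains=chains,
        factor_draws=factor_draws,
        n_rows_used=working.n if not impute else int(data.mask.any(axis=1).sum()),
        item_names=working.item_names,
    )

    if config.ppc:
        result.ppc = ppc_eigenvalues(working, factor_draws, seed=config.seed)
    if config.fit_measures:
        result.fit = bayesian_fit_measures(working, factor_draws, seed=config.seed)
    if config.std_loadings:
        result.std_loadings = standardized_loadings(
            factor_draws, config.point_estimate
        )
    if config.if_item_dropped is not None:
        for name in config.coefficients:
            result.item_dropped[name] = if_item_dropped(
                data, config, name, metric=config.if_item_dropped
            )
    return result


def frequentist_alpha(data: ItemResponseMatrix) -> float:
    """Classical point estimate of alpha from the sample covariance matrix."""
    return cronbach_alpha(sample_covariance(data))


def result_to_dict(result: AnalysisResult) -> dict:
    out: dict = {
        "config": result.config.to_dict(),
        "n_rows_used": result.n_rows_used,
        "item_names": list(result.item_names),
        "coefficients": [row.to_dict() for row in result.table],
    }
    if result.ppc is not None:
        out["ppc"] = result.ppc.to_records()
    if result.fit is not None:
        out["fit"] = result.fit.to_dict()
    if result.std_loadings is not None:
        out["std_loadings"] = [float(v) for v in result.std_loadings]
    if result.item_dropped:
        out["item_dropped"] = {
            coef: {
                "metric": idr.metric,
                "full_mean": idr.full_mean,
                "dropped_means": {k: float(v) for k, v in idr.dropped_means.items()},
                "divergences": {k: float(v) for k, v in idr.divergences.items()},
                "order": list(idr.order),
                "item_rest_correlations": {
                    k: float(v) for k, v in idr.item_rest_correlations.items()
                },
            }
            for coef, idr in result.item_dropped.items()
        }
    return out


def write_report(
    result: AnalysisResult, path: Union[str, Path], format: str = "json"
) -> list[Path]:
    """Write the analysis results to disk; returns the files written.

    JSON gives one self-contained file with the full configuration echoed
    for provenance; CSV writes one table per output into a directory.
    """
    path = Path(path)
    written: list[Path] = []
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(result_to_dict(result), fh, indent=2)
        written.append(path)
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        table = pd.DataFrame([row.to_dict() for row in result.table])
        f = path / "coefficients.csv"
        table.to_csv(f, index=False)
        written.append(f)
        if result.ppc is not None:
            f = path / "ppc.csv"
            pd.DataFrame(result.ppc.to_records()).to_csv(f, index=False)
            written.append(f)
        if result.fit is not None:
            f = path / "fit.csv"
            pd.DataFrame([result.fit.to_dict()]).to_csv(f, index=False)
            written.append(f)
        for coef, idr in result.item_dropped.items():
            f = path / f"item_dropped_{coef}.csv"
            pd.DataFrame(
                {
                    "item": list(idr.dropped_means),
                    "mean_if_dropped": list(idr.dropped_means.values()),
                    "divergence": [idr.divergences[i] for i in idr.dropped_means],
                    "item_rest_correlation": [
                        idr.item_rest_correlations[i] for i in idr.dropped_means
                    ],
                }
            ).to_csv(f, index=False)
            written.append(f)
        cfg = path / "config.json"
        with open(cfg, "w") as fh:
            json.dump(result.config.to_dict(), fh, indent=2)
        written.append(cfg)
    else:
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
    return written


def read_report(path: Union[str, Path]) -> dict:
    """Round-trip companion of :func:`write_report` for JSON reports."""
    with open(path) as fh:
        return json.load(fh)
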