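"""Analysis configuration: MCMC settings, priors, and the top-level request."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

CTT_COEFFICIENTS = ("alpha", "lambda2", "lambda6", "glb")
ALL_COEFFICIENTS = ("omega",) + CTT_COEFFICIENTS

MISSING_STRATEGIES = ("listwise", "bayes_impute")


class ConfigError(ValueError):
    """Raised when an analysis configuration is invalid."""


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout shared by every sampler.

    ``kept`` draws per chain equal ``floor((iterations - burn_in) / thin)``.
    """

    chains: int = 3
    iterations: int = 1000
    burn_in: int = 50
    thin: int = 1

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigError(f"chains must be >= 1, got {self.chains}")
        if self.thin < 1:
            raise ConfigError(f"thin must be >= 1, got {self.thin}")
        if not 0 <= self.burn_in < self.iterations:
            raise ConfigError(
                f"burn_in must satisfy 0 <= burn_in < iterations, got "
                f"burn_in={self.burn_in}, iterations={self.iterations}"
            )

    @property
    def kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class CttPrior:
    """Inverse-Wishart prior on the item covariance matrix.

    The prior scale matrix is ``scale_multiplier * I`` and the degrees of
    freedom default to the number of items (and must be at least that large).
    """

    scale_multiplier: float = 1e-10
    df: Optional[int] = None  # None -> number of items k

    def __post_init__(self) -> None:
        if self.scale_multiplier <= 0:
            raise ConfigError("scale_multiplier must be > 0")
        if self.df is not None and self.df < 1:
            raise ConfigError("df must be >= 1")

    def df_for(self, k: int) -> int:
        df = self.df if self.df is not None else k
        if df < k:
            raise ConfigError(f"prior df ({df}) must be >= number of items ({k})")
        return df


@dataclass(frozen=True)
class FactorPrior:
    """Priors for the single-factor model behind omega.

    * residual variances: inverse-gamma(shape, scale)
    * loadings: normal(loading_mean, loading_scale * psi_i) given the item's
      residual variance psi_i (the scale multiplies the residual variance)
    * latent variance: one-dimensional inverse-Wishart with scale
      ``latent_scale`` (default: number of items) and ``latent_df`` degrees of
      freedom (default: number of items + 2)
    """

    resid_shape: float = 2.0
    resid_scale: float = 1.0
    loading_mean: float = 0.0
    loading_scale: float = 1.0
    latent_scale: Optional[float] = None  # None -> k
    latent_df: Optional[int] = None  # None -> k + 2

    def __post_init__(self) -> None:
        for name in ("resid_shape", "resid_scale", "loading_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def latent_scale_for(self, k: int) -> float:
        return float(self.latent_scale) if self.latent_scale is not None else float(k)

    def latent_df_for(self, k: int) -> int:
        return int(self.latent_df) if self.latent_df is not None else k + 2


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs besides the data."""

    coefficients: tuple[str, ...] = ("omega",)
    ci_mass: float = 0.95
    prob_interval: Optional[tuple[float, float]] = None
    missing_strategy: str = "listwise"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    ctt_prior: CttPrior = field(default_factory=CttPrior)
    factor_prior: FactorPrior = field(default_factory=FactorPrior)
    point_estimate: str = "mean"
    if_item_dropped: Optional[str] = None  # None | "mean" | "kl" | "ks"
    ppc: bool = False
    fit_measures: bool = False
    std_loadings: bool = False
    n_prior_draws: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        coefs = tuple(self.coefficients)
        if not coefs:
            raise ConfigError("at least one coefficient must be requested")
        unknown = [c for c in coefs if c not in ALL_COEFFICIENTS]
        if unknown:
            raise ConfigError(
                f"unknown coefficient(s) {unknown}; choose from {ALL_COEFFICIENTS}"
            )
        if len(set(coefs)) != len(coefs):
            raise ConfigError("duplicate coefficients requested")
        object.__setattr__(self, "coefficients", coefs)
        if not 0.0 < self.ci_mass < 1.0:
            raise ConfigError(f"ci_mass must lie in (0, 1), got {self.ci_mass}")
        if self.prob_interval is not None:
            lo, hi = self.prob_interval
            if not lo < hi:
                raise ConfigError(f"prob_interval requires lo < hi, got ({lo}, {hi})")
            object.__setattr__(self, "prob_interval", (float(lo), float(hi)))
        if self.missing_strategy not in MISSING_STRATEGIES:
            raise ConfigError(
                f"missing_strategy must be one of {MISSING_STRATEGIES}, "
                f"got {self.missing_strategy!r}"
            )
        if self.point_estimate not in ("mean", "median"):
            raise ConfigError("point_estimate must be 'mean' or 'median'")
        if self.if_item_dropped not in (None, "mean", "kl", "ks"):
            raise ConfigError("if_item_dropped must be one of None, 'mean', 'kl', 'ks'")
        omega_only = {"ppc": self.ppc, "fit_measures": self.fit_measures,
                      "std_loadings": self.std_loadings}
        if "omega" not in coefs:
            bad = [name for name, on in omega_only.items() if on]
            if bad:
                raise ConfigError(
                    f"{', '.join(bad)} require(s) omega among the requested "
                    f"coefficients"
                )

    @property
    def ctt_coefficients(self) -> tuple[str, ...]:
        return tuple(c for c in self.coefficients if c in CTT_COEFFICIENTS)

    @property
    def wants_omega(self) -> bool:
        return "omega" in self.coefficients

    def to_dict(self) -> dict:
        """JSON-ready echo of the full configuration (for provenance)."""
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        if self.prob_interval is not None:
            d["prob_interval"] = list(self.prob_interval)
        return d


def config_from_mapping(mapping: dict) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a flat/nested mapping (YAML file)."""
    m = dict(mapping)
    kwargs = {}
    if "mcmc" in m:
        kwargs["mcmc"] = McmcConfig(**m.pop("mcmc"))
    if "ctt_prior" in m:
        kwargs["ctt_prior"] = CttPrior(**m.pop("ctt_prior"))
    if "factor_prior" in m:
        kwargs["factor_prior"] = FactorPrior(**m.pop("factor_prior"))
    if "coefficients" in m:
        kwargs["coefficients"] = tuple(m.pop("coefficients"))
    if "prob_interval" in m and m["prob_interval"] is not None:
        kwargs["prob_interval"] = tuple(m.pop("prob_interval"))
    kwargs.update(m)
    return AnalysisConfig(**kwargs)
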