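"""Configuration objects shared across the sampler and the effect estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel for a binary exposure: effects are computed as the full 0 -> 1
#: contrast rather than an infinitesimal rate of change.
FULL_CONTRAST = "full_contrast"


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class PriorConfig:
    """Priors for a Bayesian GLM.

    Every regression coefficient receives an independent normal prior with
    mean ``coef_mean`` and precision ``coef_precision`` (the default
    precision of 1e-6 is effectively non-informative).  Residual precisions
    of linear models receive a gamma prior with shape ``gamma_shape`` and
    rate ``gamma_rate``; the gamma prior is placed on the precision, the
    usual convention in Gibbs-sampling toolchains.
    """

    coef_mean: float = 0.0
    coef_precision: float = 1.0e-6
    gamma_shape: float = 1.0
    gamma_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("coef_precision", "gamma_shape", "gamma_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC run length and reproducibility settings.

    Defaults follow the common single-chain workflow: 11,000 iterations with
    the first 1,000 discarded as burn-in and no thinning, which retains
    10,000 posterior draws.
    """

    n_iter: int = 11_000
    burn_in: int = 1_000
    n_chains: int = 1
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.n_iter <= 0 or self.n_chains <= 0 or self.thin <= 0:
            raise ConfigError("n_iter, n_chains and thin must be positive")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class DeltaConfig:
    """Step sizes for the difference-quotient estimators.

    ``dx`` is the exposure step: for a binary exposure the full 0 -> 1
    contrast is used (``FULL_CONTRAST``); for a continuous exposure the
    default rule is min(0.01, range(X)/100).  ``dm`` is the analogous
    mediator step with rule min(0.01, range(M)/100), resolved per mediator.
    """

    dx: Optional[float | str] = None
    dm: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.dx, (int, float)) and self.dx <= 0:
            raise ConfigError("dx must be strictly positive")
        if self.dm is not None and self.dm <= 0:
            raise ConfigError("dm must be strictly positive")


def delta_rule(values_range: float) -> float:
    """Default step: the minimum of 0.01 and the variable's range / 100."""
    return min(0.01, values_range / 100.0)
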