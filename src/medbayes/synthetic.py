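"""Registry-like synthetic datasets with known mediation structure.

The generator emulates the structure of a tumor-registry disparity study:
a binary exposure (race-like, prevalence ~30.6%), a continuous age-like
outcome, categorical mediators driven by baseline-category logits in the
exposure, and continuous mediators with exposure-dependent means (optionally
correlated residuals).  Every dataset carries exact ground-truth total,
direct and indirect effects for a linear outcome, so estimator recovery can
be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import MediationDataset, MediatorSpec

__all__ = [
    "ContinuousMediatorSim",
    "CategoricalMediatorSim",
    "OutcomeSim",
    "SyntheticConfig",
    "generate",
    "true_effects",
    "default_template",
    "binary_outcome_template",
]


@dataclass(frozen=True)
class ContinuousMediatorSim:
    """Linear mediator model ``M = intercept + a * X + noise``."""

    name: str
    intercept: float = 0.0
    a: float = 0.0
    sd: float = 1.0
    group: Optional[str] = None
    forced: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"mediator {self.name!r}: sd must be > 0")


@dataclass(frozen=True)
class CategoricalMediatorSim:
    """Baseline-category logit mediator with K levels.

    ``a0`` and ``a`` hold the K-1 intercepts and exposure slopes of the log
    odds of each non-reference level against the reference (the first
    level): ``log P(level_k) / P(level_0) = a0_k + a_k * X``.
    """

    name: str
    levels: tuple
    a0: tuple
    a: tuple
    group: Optional[str] = None
    forced: bool = False

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"mediator {self.name!r}: need >= 2 levels")
        if len(self.a0) != len(self.levels) - 1 or len(self.a) != len(self.levels) - 1:
            raise ValueError(
                f"mediator {self.name!r}: a0 and a must have K-1 = "
                f"{len(self.levels) - 1} entries"
            )

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        """Category probabilities per subject, columns ordered like levels."""
        eta = np.column_stack(
            [np.zeros(len(x))]
            + [a0 + a * x for a0, a in zip(self.a0, self.a)]
        )
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        if np.any(p.sum(axis=1) == 0) or not np.isfinite(p).all():
            raise ValueError(f"mediator {self.name!r}: degenerate category probabilities")
        return p


@dataclass(frozen=True)
class OutcomeSim:
    """Outcome model: linear (age-like) or logistic.

    ``b`` maps each mediator name to its outcome coefficient — a float for
    continuous mediators, or a per-non-reference-level dict for categorical
    ones.  ``c`` is the direct exposure effect.
    """

    intercept: float = 62.0
    c: float = 0.0
    b: Dict[str, object] = field(default_factory=dict)
    sd: float = 12.0
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.sd <= 0:
            raise ValueError("outcome sd must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full ground-truth specification of a synthetic mediation dataset."""

    n: int = 2275
    exposure_prevalence: float = 696 / 2275
    #: "binary" draws a Bernoulli(prevalence) exposure; "continuous" a
    #: standard-normal one (prevalence then unused)
    exposure_kind: str = "binary"
    mediators: tuple = ()
    outcome: OutcomeSim = field(default_factory=OutcomeSim)
    seed: int = 0
    #: correlation between the noise terms of consecutive continuous
    #: mediators listed in ``corr_pairs`` (name_a, name_b, rho)
    corr_pairs: tuple = ()
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        if self.exposure_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown exposure kind {self.exposure_kind!r}")
        if not 0 < self.exposure_prevalence < 1:
            raise ValueError("exposure_prevalence must be in (0, 1)")
        if self.n < 10:
            raise ValueError("n too small")
        names = [m.name for m in self.mediators]
        if len(set(names)) != len(names):
            raise ValueError("duplicate mediator names")
        for a, b, rho in self.corr_pairs:
            if not -1 < rho < 1:
                raise ValueError("correlations must lie in (-1, 1)")
            if a not in names or b not in names:
                raise ValueError(f"corr_pair ({a}, {b}) names unknown mediators")

    def to_yaml(self, path) -> None:
        """Dump the configuration (for provenance capture)."""
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, default_flow_style=False)


def _mediator_spec(m) -> MediatorSpec:
    if isinstance(m, ContinuousMediatorSim):
        return MediatorSpec(m.name, "continuous", forced=m.forced, group=m.group)
    return MediatorSpec(m.name, "categorical", levels=tuple(m.levels),
                        reference_level=m.levels[0], forced=m.forced, group=m.group)


def generate(config: SyntheticConfig) -> MediationDataset:
    """Draw one dataset from the configured ground-truth models."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if config.exposure_kind == "binary":
        x = (rng.random(n) < config.exposure_prevalence).astype(float)
    else:
        x = rng.standard_normal(n)

    cont = [m for m in config.mediators if isinstance(m, ContinuousMediatorSim)]
    noise = {m.name: rng.standard_normal(n) for m in cont}
    for a, b, rho in config.corr_pairs:
        # correlate b's noise with a's, keeping unit marginal variance
        noise[b] = rho * noise[a] + np.sqrt(1 - rho ** 2) * noise[b]

    cols = {config.exposure_name: x}
    for m in config.mediators:
        if isinstance(m, ContinuousMediatorSim):
            cols[m.name] = m.intercept + m.a * x + m.sd * noise[m.name]
        else:
            p = m.probabilities(x)
            u = rng.random(n)
            codes = (u[:, None] >= p.cumsum(axis=1)).sum(axis=1)
            cols[m.name] = np.asarray(m.levels, dtype=object)[codes]

    eta = config.outcome.intercept + config.outcome.c * x
    for m in config.mediators:
        coef = config.outcome.b.get(m.name, 0.0)
        if isinstance(m, ContinuousMediatorSim):
            eta = eta + coef * cols[m.name]
        else:
            for lv, b_k in (coef or {}).items():
                eta = eta + b_k * (cols[m.name] == lv)
    if config.outcome.kind == "continuous":
        y = eta + config.outcome.sd * rng.standard_normal(n)
    else:
        from scipy.special import expit
        y = (rng.random(n) < expit(eta)).astype(float)

    cols[config.outcome_name] = y
    frame = pd.DataFrame(cols)
    specs = [_mediator_spec(m) for m in config.mediators]
    return MediationDataset(frame, config.exposure_name, config.outcome_name, specs,
                            outcome_kind=config.outcome.kind)


def true_effects(config: SyntheticConfig) -> Dict[str, object]:
    """Exact ground-truth effects for a linear outcome (0 -> 1 contrast).

    Continuous mediator: ``IE = a * b``.  Categorical mediator:
    ``IE = sum_k b_k * (P_k(x=1) - P_k(x=0))`` through the multinomial
    inverse link.  ``DE = c`` and ``TE = DE + sum IE``.  Group labels map to
    the sum of their members' effects.
    """
    if config.outcome.kind != "continuous":
        raise ValueError(
            "closed-form ground truth requires a linear outcome; use a "
            "large-sample Monte-Carlo oracle for nonlinear outcomes"
        )
    ie: Dict[str, float] = {}
    groups: Dict[str, float] = {}
    for m in config.mediators:
        coef = config.outcome.b.get(m.name, 0.0)
        if isinstance(m, ContinuousMediatorSim):
            val = m.a * coef
        else:
            p = m.probabilities(np.array([0.0, 1.0]))
            val = 0.0
            for k, lv in enumerate(m.levels):
                b_k = (coef or {}).get(lv, 0.0)
                val += b_k * (p[1, k] - p[0, k])
        ie[m.name] = float(val)
        if m.group is not None:
            groups[m.group] = groups.get(m.group, 0.0) + float(val)
    de = float(config.outcome.c)
    te = de + sum(ie.values())
    return {"te": te, "de": de, "ie": ie, "groups": groups}


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def default_template(n: int = 2275, seed: int = 0) -> SyntheticConfig:
    """Registry-like template: binary exposure at prevalence 696/2275, an
    age-like continuous outcome (intercept 62, residual sd 12), one 3-level
    insurance-like and one 4-level marital-like categorical mediator, and
    two correlated continuous environment-like mediators sharing a group
    label so joint-effect logic is exercised."""
    mediators = (
        CategoricalMediatorSim(
            "insurance", levels=("none", "public", "private"),
            a0=(0.5, 1.5), a=(1.0, -1.0),
        ),
        CategoricalMediatorSim(
            "marital", levels=("single", "married", "separated", "widowed"),
            a0=(1.0, 0.2, 0.3), a=(-1.0, -0.4, -0.2),
        ),
        ContinuousMediatorSim("street_density", intercept=10.0, a=5.0, sd=8.0,
                              group="walkability", forced=True),
        ContinuousMediatorSim("node_ratio", intercept=0.63, a=0.08, sd=0.13,
                              group="walkability", forced=True),
    )
    outcome = OutcomeSim(
        intercept=62.0, c=-4.0,
        b={
            "insurance": {"public": 1.0, "private": 2.0},
            "marital": {"married": 1.5, "separated": -0.5, "widowed": 0.5},
            "street_density": -0.05,
            "node_ratio": -3.0,
        },
        sd=12.0, kind="continuous",
    )
    return SyntheticConfig(
        n=n, mediators=mediators, outcome=outcome, seed=seed,
        corr_pairs=(("street_density", "node_ratio", 0.5),),
    )


def binary_outcome_template(n: int = 2000, seed: int = 0) -> SyntheticConfig:
    """Logistic-outcome template exercising the logit branch: a continuous
    exposure and a single continuous mediator transmitting the whole effect
    (no direct pathway), so the analytic and re-sampling estimators share
    one estimand exactly."""
    mediators = (
        ContinuousMediatorSim("m1", intercept=0.0, a=0.6, sd=1.0),
    )
    outcome = OutcomeSim(intercept=-0.3, c=0.0, b={"m1": 0.7}, sd=1.0, kind="binary")
    return SyntheticConfig(n=n, mediators=mediators, outcome=outcome, seed=seed,
                           exposure_kind="continuous")
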