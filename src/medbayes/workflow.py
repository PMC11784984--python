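"""End-to-end analysis pipeline: screening -> model fitting -> effects -> report.

:func:`run` chains the stages on a CSV data file described by a
:class:`RunConfig` (usually loaded from YAML), writes a report bundle —
effect tables, screening report, posterior draws, diagnostics and a run
log — and returns the in-memory results.  Every number in the written
report is a pure summary of the exported posterior draws, and reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, DeltaConfig, MCMCConfig, PriorConfig
from .data import MediationDataset, MediatorSpec
from .estimators import (EffectDraws, EffectSummary, method1_effects,
                         method2_effects, method3_effects, summarize)
from .sampler import PosteriorDraws, diagnostics, fit_linear, fit_logistic, fit_multinomial
from .screening import ScreeningReport, screen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run", "fit_models", "plot_posteriors"]


@dataclass
class RunConfig:
    """Declarative description of one mediation analysis run."""

    data: str
    exposure: str
    outcome: str
    mediators: List[dict]
    outcome_kind: str = "continuous"
    covariates: List[str] = field(default_factory=list)
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    delta: DeltaConfig = field(default_factory=DeltaConfig)
    methods: List[int] = field(default_factory=lambda: [3])
    alpha: float = 0.1
    do_screen: bool = True
    level: float = 0.95
    seed: int = 0
    outdir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not set(self.methods) <= {1, 2, 3}:
            raise ConfigError(f"methods must be a subset of {{1, 2, 3}}, got {self.methods}")
        if not self.mediators:
            raise ConfigError("at least one mediator must be declared")
        names = [m["name"] for m in self.mediators]
        if self.exposure in names or self.outcome in names:
            raise ConfigError("exposure/outcome must not be declared as mediators")
        if self.exposure == self.outcome:
            raise ConfigError("exposure and outcome must name different columns")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, ctor in (("prior", PriorConfig), ("mcmc", MCMCConfig), ("delta", DeltaConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ctor(**raw[key])
        return cls(**raw)

    def mediator_specs(self) -> List[MediatorSpec]:
        specs = []
        for m in self.mediators:
            m = dict(m)
            if "levels" in m and m["levels"] is not None:
                m["levels"] = tuple(m["levels"])
            specs.append(MediatorSpec(**m))
        return specs

    def snapshot(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, default_flow_style=False)


@dataclass
class ReportBundle:
    """Everything one run produced."""

    data: MediationDataset
    screening: Optional[ScreeningReport]
    outcome_draws: PosteriorDraws
    mediator_draws: Dict[str, PosteriorDraws]
    effects: Dict[int, EffectDraws]
    summaries: Dict[int, EffectSummary]
    log_lines: List[str]


def _derived_seed(seed: int, index: int) -> int:
    """Stable 31-bit seed for stage ``index`` of a run with root ``seed``."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))


def fit_models(data: MediationDataset, prior: PriorConfig, mcmc: MCMCConfig,
               mediator_covariates: Sequence[str] = ()):
    """Fit the outcome model and one model per mediator.

    The outcome model is linear (continuous outcome) or logistic (binary);
    each mediator is regressed on the exposure — plus any
    ``mediator_covariates``, which default to none — with the model matching
    its kind.  Per-model seeds are derived from ``mcmc.seed`` so the whole
    fit is reproducible from a single integer.
    """
    root = mcmc.seed
    ydesign = data.outcome_design()
    y = data.outcome.to_numpy(dtype=float)
    out_mcmc = dataclasses.replace(mcmc, seed=_derived_seed(root, 0))
    if data.outcome_kind == "binary":
        outcome_draws = fit_logistic(y, ydesign, prior, out_mcmc)
    else:
        outcome_draws = fit_linear(y, ydesign, prior, out_mcmc)

    mdesign = data.mediator_design(mediator_covariates)
    mediator_draws: Dict[str, PosteriorDraws] = {}
    for i, (name, spec) in enumerate(data.mediators.items(), start=1):
        m_mcmc = dataclasses.replace(mcmc, seed=_derived_seed(root, i))
        col = data.mediator_values(name)
        if spec.kind == "continuous":
            mediator_draws[name] = fit_linear(col.to_numpy(dtype=float), mdesign,
                                              prior, m_mcmc)
        elif spec.kind == "binary":
            mediator_draws[name] = fit_logistic(col.to_numpy(dtype=float), mdesign,
                                                prior, m_mcmc)
        else:
            mediator_draws[name] = fit_multinomial(col.to_numpy(), mdesign, prior,
                                                   m_mcmc, reference=spec.reference_level)
    return outcome_draws, mediator_draws


def _estimate(method: int, outcome_draws, mediator_draws, data, delta, seed) -> EffectDraws:
    if method == 1:
        return method1_effects(outcome_draws, mediator_draws, data, delta)
    if method == 2:
        return method2_effects(outcome_draws, mediator_draws, data, delta)
    return method3_effects(outcome_draws, mediator_draws, data, delta, resample_seed=seed)


def run(config: RunConfig) -> ReportBundle:
    """Execute a full analysis and (optionally) write the report bundle."""
    t0 = time.time()
    log: List[str] = []

    def stage(msg: str) -> None:
        line = f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] (+{time.time() - t0:6.1f}s) {msg}"
        log.append(line)
        logger.info(msg)

    specs = config.mediator_specs()
    data = MediationDataset.from_csv(config.data, config.exposure, config.outcome,
                                     specs, covariates=config.covariates,
                                     outcome_kind=config.outcome_kind)
    stage(f"loaded {config.data}: n={data.n}, {len(specs)} candidate mediators, "
          f"seed={config.seed}")

    screening = None
    if config.do_screen:
        screening = screen(data, alpha=config.alpha)
        kept = screening.included
        stage(f"screening at alpha={config.alpha}: kept {kept}")
        if not kept:
            raise RuntimeError("screening excluded every candidate mediator")
        if set(kept) != set(data.mediators):
            data = MediationDataset(data.frame, config.exposure, config.outcome,
                                    [data.mediators[k] for k in kept],
                                    covariates=config.covariates,
                                    outcome_kind=config.outcome_kind)

    mcmc = dataclasses.replace(config.mcmc, seed=_derived_seed(config.seed, 1001))
    outcome_draws, mediator_draws = fit_models(data, config.prior, mcmc)
    stage(f"fitted outcome model ({outcome_draws.model_kind}) and "
          f"{len(mediator_draws)} mediator models; "
          f"{outcome_draws.n_retained} retained draws each")

    effects: Dict[int, EffectDraws] = {}
    summaries: Dict[int, EffectSummary] = {}
    for m in sorted(set(config.methods)):
        effects[m] = _estimate(m, outcome_draws, mediator_draws, data, config.delta,
                               seed=_derived_seed(config.seed, 1002))
        summaries[m] = summarize(effects[m], level=config.level)
        stage(f"method {m}: TE={effects[m].te.mean():.4f}, DE={effects[m].de.mean():.4f}")

    bundle = ReportBundle(data=data, screening=screening, outcome_draws=outcome_draws,
                          mediator_draws=mediator_draws, effects=effects,
                          summaries=summaries, log_lines=log)
    if config.outdir is not None:
        _write_bundle(bundle, config)
        stage(f"report bundle written to {config.outdir}")
    return bundle


def _write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    (outdir / "draws").mkdir(parents=True, exist_ok=True)
    config.snapshot(outdir / "config_snapshot.yaml")

    if bundle.screening is not None:
        bundle.screening.to_csv(outdir / "screening.csv")

    tables = []
    for m, summ in bundle.summaries.items():
        summ.to_csv(outdir / f"effects_method{m}.csv")
        tables.append(summ.table)
    if tables:
        combined = pd.concat(tables, ignore_index=True)
        combined.to_csv(outdir / "effects.csv", index=False)
        combined.to_json(outdir / "effects.json", orient="records", indent=2)

    bundle.outcome_draws.to_csv(outdir / "draws" / "outcome.csv")
    for name, d in bundle.mediator_draws.items():
        d.to_csv(outdir / "draws" / f"mediator_{name}.csv")
    for m, eff in bundle.effects.items():
        eff.to_frame().to_csv(outdir / "draws" / f"effects_method{m}.csv", index=False)

    with open(outdir / "diagnostics.txt", "w") as fh:
        fh.write("== outcome model ==\n")
        fh.write(diagnostics(bundle.outcome_draws).to_string())
        for name, d in bundle.mediator_draws.items():
            fh.write(f"\n\n== mediator model: {name} ==\n")
            fh.write(diagnostics(d).to_string())
            for w in d.warnings:
                fh.write(f"\nWARNING: {w}")
        fh.write("\n")

    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(bundle.log_lines) + "\n")

    if config.make_plots:
        for m, eff in bundle.effects.items():
            plot_posteriors(eff, outdir / "figures" / f"method{m}")
        plot_posteriors(bundle.outcome_draws, outdir / "figures" / "outcome_model")


def plot_posteriors(obj, outdir, bins: int = 50) -> List[Path]:
    """Posterior histograms (and traces for coefficient draws).

    ``obj`` may be an :class:`EffectDraws` — one histogram per effect — or a
    :class:`PosteriorDraws` — histogram plus trace per coefficient.  Returns
    the written file paths; an empty effect map writes nothing and logs a
    warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: List[Path] = []

    def hist(values, title, path):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(values, bins=bins, color="#4477aa", edgecolor="white")
        ax.axvline(0.0, color="black", lw=0.8, ls="--")
        ax.set_title(title)
        ax.set_xlabel("posterior draw")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    if isinstance(obj, EffectDraws):
        series = {"total_effect": obj.te, "direct_effect": obj.de}
        series.update({f"indirect_{k}": v for k, v in obj.ie.items()})
        if not obj.ie:
            warnings.warn("no indirect-effect draws to plot", stacklevel=2)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, v in series.items():
            hist(v, key.replace("_", " "), outdir / f"{key}.png")
        return written

    if isinstance(obj, PosteriorDraws):
        outdir.mkdir(parents=True, exist_ok=True)
        for j, name in enumerate(obj.coef_names):
            col = obj.coef_draws[:, j]
            safe = name.replace(":", "_").replace("[", "_").replace("]", "")
            hist(col, name, outdir / f"coef_{safe}.png")
            fig, ax = plt.subplots(figsize=(6, 2.4))
            ax.plot(col, lw=0.4)
            ax.set_title(f"trace: {name}")
            ax.set_xlabel("retained draw")
            fig.tight_layout()
            path = outdir / f"trace_{safe}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        return written

    raise TypeError("plot_posteriors expects EffectDraws or PosteriorDraws")
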