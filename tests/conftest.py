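import numpy as np
import pandas as pd
import pytest

import medbayes as mb
from medbayes.sampler import PosteriorDraws


def make_const_draws(names, values, kind="linear", n=200, levels=None):
    """PosteriorDraws whose every retained draw equals ``values`` — lets
    estimator arithmetic be checked against hand-computed numbers."""
    arr = np.tile(np.asarray(values, dtype=float), (n, 1))
    disp = np.ones(n) if kind == "linear" else None
    return PosteriorDraws(kind, list(names), arr, dispersion_draws=disp, levels=levels)


def linear_dataset(n=400, a=0.5, b=0.4, c=1.0, seed=0, med_sd=1.0, y_sd=1.0,
                   exposure="binary"):
    """One continuous mediator, linear outcome, known coefficients."""
    rng = np.random.default_rng(seed)
    if exposure == "binary":
        x = rng.binomial(1, 0.4, n).astype(float)
    else:
        x = rng.standard_normal(n)
    m = a * x + med_sd * rng.standard_normal(n)
    y = 2.0 + c * x + b * m + y_sd * rng.standard_normal(n)
    frame = pd.DataFrame({"x": x, "m": m, "y": y})
    return mb.MediationDataset(frame, "x", "y", [mb.MediatorSpec("m", "continuous")])


@pytest.fixture(scope="session")
def registry_fit():
    """Registry-like fixture with categorical + grouped continuous mediators,
    fitted once and shared across estimator tests."""
    cfg = mb.default_template(n=1500, seed=42)
    data = mb.generate(cfg)
    mcmc = mb.MCMCConfig(n_iter=1500, burn_in=500, seed=7)
    outcome_draws, mediator_draws = mb.fit_models(data, mb.PriorConfig(), mcmc)
    return cfg, data, outcome_draws, mediator_draws


@pytest.fixture(scope="session")
def linear_fit():
    """All-linear three-mediator fixture fitted once (cross-method tests)."""
    mediators = (
        mb.ContinuousMediatorSim("m1", intercept=1.0, a=0.8, sd=1.0),
        mb.ContinuousMediatorSim("m2", intercept=-0.5, a=-0.6, sd=1.2, group="pair"),
        mb.ContinuousMediatorSim("m3", intercept=0.0, a=0.5, sd=0.8, group="pair"),
    )
    outcome = mb.OutcomeSim(intercept=5.0, c=1.0,
                            b={"m1": -0.5, "m2": 0.4, "m3": 0.6}, sd=1.5)
    cfg = mb.SyntheticConfig(n=1200, mediators=mediators, outcome=outcome, seed=11)
    data = mb.generate(cfg)
    mcmc = mb.MCMCConfig(n_iter=2200, burn_in=200, seed=13)
    outcome_draws, mediator_draws = mb.fit_models(data, mb.PriorConfig(), mcmc)
    return cfg, data, outcome_draws, mediator_draws
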