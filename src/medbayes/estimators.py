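"""Total, direct and indirect effect estimation from posterior draws.

Three estimators share the same inputs — posterior draws for the outcome
model, posterior draws for each mediator model, and the subject-level data —
and produce per-draw effect values:

* **Method 1 (functions of coefficients).**  Effects are analytic functions
  of the model coefficients.  For an all-linear system the indirect effect
  of a continuous mediator is the product ``a*b`` of the exposure->mediator
  and mediator->outcome coefficients; categorical mediators contribute
  ``sum_k b_k * dP_k/dx``; a logistic outcome weights the coefficient
  functions by the mean derivative of the inverse-logit at the observed
  linear predictor.
* **Method 2 (product of partial differences).**  Derivatives are replaced
  by difference quotients of posterior predictive means, with steps
  ``dx``/``dm`` resolved by the min(0.01, range/100) rule for continuous
  variables and the full 0 -> 1 contrast for a binary exposure.
* **Method 3 (re-sampling).**  The total effect contrasts outcome
  predictions with every mediator responding to the exposure shift; the
  direct effect holds mediators at draws from their empirical marginal
  (whole rows resampled jointly, preserving inter-mediator correlation);
  each indirect effect is the total-minus-direct difference with only the
  mediator (or mediator group) of interest responding.

Per-draw effect vectors are summarized into posterior means, equal-tailed
credible sets, and relative effects (per-draw percentages of the total
effect), mirroring the usual mediation report layout.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DeltaConfig, FULL_CONTRAST, delta_rule
from .data import INTERCEPT, MediationDataset, MediatorSpec, dummy_name
from .sampler import PosteriorDraws

__all__ = [
    "EffectDraws",
    "EffectSummary",
    "method1_effects",
    "method2_effects",
    "method3_effects",
    "joint_effect",
    "summarize",
]

_CHUNK = 256  # draws evaluated per block; bounds memory at ~chunk x n doubles


@dataclass
class EffectDraws:
    """Per-draw total, direct and indirect effects.

    ``ie`` maps each mediator name — and each declared group label — to its
    draw vector.  ``groups`` records which keys are groups and their members.
    """

    te: np.ndarray
    de: np.ndarray
    ie: Dict[str, np.ndarray]
    method: int
    groups: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.te)
        if len(self.de) != n or any(len(v) != n for v in self.ie.values()):
            raise ValueError("all effect draw vectors must have equal length")

    @property
    def n_retained(self) -> int:
        return len(self.te)

    @property
    def mediator_names(self) -> List[str]:
        return [k for k in self.ie if k not in self.groups]

    def to_frame(self) -> pd.DataFrame:
        cols = {"te": self.te, "de": self.de}
        cols.update({f"ie:{k}": v for k, v in self.ie.items()})
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# model wrappers: evaluate predictive means at counterfactual inputs
# ---------------------------------------------------------------------------

def _rows(a) -> np.ndarray:
    """Promote (n,) arrays to a broadcastable (1, n) row."""
    a = np.asarray(a, dtype=float)
    return a[None, :] if a.ndim == 1 else a


class _OutcomeModel:
    """Maps coefficient draws + counterfactual inputs to linear predictors."""

    def __init__(self, draws: PosteriorDraws, data: MediationDataset):
        if draws.model_kind not in ("linear", "logistic"):
            raise ValueError(
                f"outcome model kind {draws.model_kind!r} is not supported; "
                "use a linear or logistic outcome model"
            )
        self.kind = draws.model_kind
        self.draws = draws
        names = draws.coef_names
        self.i_idx = names.index(INTERCEPT)
        self.x_idx = names.index(data.exposure_name)
        self.med_cols: Dict[str, object] = {}
        for spec in data.mediators.values():
            if spec.kind == "continuous":
                self.med_cols[spec.name] = names.index(spec.name)
            elif spec.kind == "binary":
                self.med_cols[spec.name] = {1: names.index(spec.name)}
            else:
                self.med_cols[spec.name] = {
                    lv: names.index(dummy_name(spec.name, lv))
                    for lv in spec.nonreference_levels
                }
        self.cov_terms = [
            (names.index(c), data.frame[c].to_numpy(dtype=float)) for c in data.covariates
        ]

    def eta(self, sl: slice, x, med_vals: Mapping[str, object]) -> np.ndarray:
        """Linear predictor, shape (chunk, n)."""
        coefs = self.draws.coef_draws[sl]
        eta = coefs[:, self.i_idx][:, None] + coefs[:, self.x_idx][:, None] * _rows(x)
        for name, cols in self.med_cols.items():
            v = med_vals[name]
            if isinstance(cols, dict):
                for lv, idx in cols.items():
                    eta = eta + coefs[:, idx][:, None] * _rows(v[lv])
            else:
                eta = eta + coefs[:, cols][:, None] * _rows(v)
        for idx, vals in self.cov_terms:
            eta = eta + coefs[:, idx][:, None] * vals[None, :]
        return eta

    def mean_f(self, sl: slice, x, med_vals) -> np.ndarray:
        """Predictive mean averaged over subjects, one value per draw."""
        eta = self.eta(sl, x, med_vals)
        if self.kind == "logistic":
            eta = expit(eta)
        return eta.mean(axis=1)

    def mean_weight(self, sl: slice, x, med_vals) -> np.ndarray:
        """Mean inverse-logit derivative expit(eta)(1-expit(eta)) per draw."""
        p = expit(self.eta(sl, x, med_vals))
        return (p * (1.0 - p)).mean(axis=1)


class _MediatorModel:
    """Predictive means / category probabilities of one mediator model."""

    def __init__(self, draws: PosteriorDraws, spec: MediatorSpec,
                 data: MediationDataset):
        self.spec = spec
        self.draws = draws
        expected = {
            "continuous": "linear", "binary": "logistic", "categorical": "multinomial",
        }[spec.kind]
        if draws.model_kind != expected:
            raise ValueError(
                f"mediator {spec.name!r} is {spec.kind} but its model is "
                f"{draws.model_kind!r} (expected {expected!r})"
            )
        if spec.kind == "categorical":
            block = [c.split(":", 1)[1] for c in draws.coef_names[: _block_width(draws)]]
            names = block
            self._nonref = list(draws.levels[1:])
            self._ref = draws.levels[0]
            if set(draws.levels) != set(spec.levels):
                raise ValueError(
                    f"mediator {spec.name!r}: fitted levels {draws.levels} do not "
                    f"match declared levels {spec.levels}"
                )
        else:
            names = list(draws.coef_names)
        self.i_idx = names.index(INTERCEPT)
        self.x_idx = names.index(data.exposure_name)
        # any further design column is an extra mediator-model covariate,
        # held at its observed values in every counterfactual evaluation
        extra = [c for c in names if c not in (INTERCEPT, data.exposure_name)]
        missing = [c for c in extra if c not in data.frame.columns]
        if missing:
            raise ValueError(
                f"mediator {spec.name!r}: model covariates {missing} not in the data"
            )
        self.cov_terms = [
            (names.index(c), data.frame[c].to_numpy(dtype=float)) for c in extra
        ]
        self._p = len(names)

    # continuous -----------------------------------------------------------
    def mean_value(self, sl: slice, x) -> np.ndarray:
        assert self.spec.kind == "continuous"
        coefs = self.draws.coef_draws[sl]
        out = coefs[:, self.i_idx][:, None] + coefs[:, self.x_idx][:, None] * _rows(x)
        for idx, vals in self.cov_terms:
            out = out + coefs[:, idx][:, None] * vals[None, :]
        return out

    # binary / categorical ---------------------------------------------------
    def probs(self, sl: slice, x) -> Dict[object, np.ndarray]:
        """Category probabilities per draw and subject, all levels."""
        coefs = self.draws.coef_draws[sl]
        if self.spec.kind == "binary":
            eta = coefs[:, self.i_idx][:, None] + coefs[:, self.x_idx][:, None] * _rows(x)
            for idx, vals in self.cov_terms:
                eta = eta + coefs[:, idx][:, None] * vals[None, :]
            p1 = expit(eta)
            return {1: p1, 0: 1.0 - p1}
        p = self._p
        etas = []
        for k in range(len(self._nonref)):
            blk = coefs[:, k * p:(k + 1) * p]
            eta = blk[:, self.i_idx][:, None] + blk[:, self.x_idx][:, None] * _rows(x)
            for idx, vals in self.cov_terms:
                eta = eta + blk[:, idx][:, None] * vals[None, :]
            etas.append(eta)
        stack = np.stack([np.zeros_like(etas[0]), *etas])  # K x chunk x n
        stack = np.exp(stack - stack.max(axis=0, keepdims=True))
        stack /= stack.sum(axis=0, keepdims=True)
        return {lv: stack[i] for i, lv in enumerate((self._ref, *self._nonref))}

    def sample_weights(self, sl: slice, x, u: np.ndarray) -> Dict[object, np.ndarray]:
        """Sample categories with common uniforms ``u``; indicator arrays for
        the non-reference levels (reference implied)."""
        probs = self.probs(sl, x)
        levels = self.level_order
        cum = np.zeros_like(u)
        codes = np.zeros(u.shape, dtype=np.int64)
        for i, lv in enumerate(levels[:-1]):
            cum = cum + probs[lv]
            codes += (u >= cum).astype(np.int64)
        return {
            lv: (codes == i).astype(float)
            for i, lv in enumerate(levels)
            if lv != self.reference
        }

    @property
    def level_order(self) -> List[object]:
        if self.spec.kind == "binary":
            return [0, 1]
        return [self._ref, *self._nonref]

    @property
    def reference(self):
        return 0 if self.spec.kind == "binary" else self._ref

    def observed_weights(self, values: np.ndarray) -> Dict[object, np.ndarray]:
        """Indicator representation of observed categories."""
        return {
            lv: (values == lv).astype(float)
            for lv in self.level_order
            if lv != self.reference
        }


def _block_width(draws: PosteriorDraws) -> int:
    return draws.coef_draws.shape[1] // (len(draws.levels) - 1)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _exposure_arms(data: MediationDataset, delta: Optional[DeltaConfig]):
    """Return (x_base, x_shifted, dx) arrays used in the contrasts."""
    x = data.exposure.to_numpy(dtype=float)
    dx_setting = delta.dx if delta is not None else None
    if data.exposure_binary and (dx_setting is None or dx_setting == FULL_CONTRAST):
        return np.zeros_like(x), np.ones_like(x), 1.0
    if dx_setting is None or dx_setting == FULL_CONTRAST:
        dx = delta_rule(float(np.ptp(x)))
    else:
        dx = float(dx_setting)
    return x, x + dx, dx


def _resolve_dm(data: MediationDataset, name: str, delta: Optional[DeltaConfig]) -> float:
    if delta is not None and delta.dm is not None:
        return float(delta.dm)
    return delta_rule(float(np.ptp(data.mediator_values(name).to_numpy(dtype=float))))


def _wrap_models(outcome_draws, mediator_draws, data):
    out = _OutcomeModel(outcome_draws, data)
    meds = {}
    for name, spec in data.mediators.items():
        if name not in mediator_draws:
            raise KeyError(f"no fitted model supplied for mediator {name!r}")
        meds[name] = _MediatorModel(mediator_draws[name], spec, data)
    return out, meds


def _observed_values(data: MediationDataset, meds: Dict[str, _MediatorModel]):
    vals: Dict[str, object] = {}
    for name, mm in meds.items():
        col = data.mediator_values(name).to_numpy()
        if mm.spec.kind == "continuous":
            vals[name] = col.astype(float)
        else:
            vals[name] = mm.observed_weights(col)
    return vals


def _chunks(n_draws: int, size: int = _CHUNK):
    for start in range(0, n_draws, size):
        yield slice(start, min(start + size, n_draws))


def _add_group_sums(ie: Dict[str, np.ndarray], groups: Dict[str, List[str]]):
    for g, members in groups.items():
        ie[g] = np.sum([ie[m] for m in members], axis=0)


# ---------------------------------------------------------------------------
# Method 1: functions of coefficients
# ---------------------------------------------------------------------------

def method1_effects(outcome_draws: PosteriorDraws,
                    mediator_draws: Mapping[str, PosteriorDraws],
                    data: MediationDataset,
                    delta: Optional[DeltaConfig] = None) -> EffectDraws:
    """Analytic coefficient-function estimator.

    Linear outcome: ``IE = a*b`` for continuous mediators, the direct effect
    is the exposure coefficient, and categorical mediators contribute the
    coefficient-weighted change in category probabilities.  Logistic
    outcome: the same coefficient functions scaled by the mean logistic
    derivative at the observed linear predictor.
    """
    out, meds = _wrap_models(outcome_draws, mediator_draws, data)
    x0, x1, dx = _exposure_arms(data, delta)
    nd = outcome_draws.n_retained
    obs = _observed_values(data, meds)
    x_obs = data.exposure.to_numpy(dtype=float)

    c_draws = outcome_draws.coef(data.exposure_name)
    if out.kind == "logistic":
        wbar = np.empty(nd)
        for sl in _chunks(nd):
            wbar[sl] = out.mean_weight(sl, x_obs, obs)
    else:
        wbar = np.ones(nd)

    de = c_draws * wbar
    ie: Dict[str, np.ndarray] = {}
    for name, mm in meds.items():
        if mm.spec.kind == "continuous":
            a = mediator_draws[name].coef(data.exposure_name)
            b = outcome_draws.coef(name)
            ie[name] = a * b * wbar
        else:
            vec = np.empty(nd)
            cols = out.med_cols[name]  # level -> outcome coefficient index
            for sl in _chunks(nd):
                p1 = mm.probs(sl, x1)
                p0 = mm.probs(sl, x0)
                acc = np.zeros(sl.stop - sl.start)
                for lv, idx in cols.items():
                    b_k = outcome_draws.coef_draws[sl, idx]
                    acc += b_k * ((p1[lv] - p0[lv]).mean(axis=1) / dx)
                vec[sl] = acc
            ie[name] = vec * wbar

    te = de + np.sum(list(ie.values()), axis=0) if ie else de.copy()
    _add_group_sums(ie, data.groups)
    return EffectDraws(te=te, de=de, ie=ie, method=1, groups=data.groups)


# ---------------------------------------------------------------------------
# Method 2: product of partial differences
# ---------------------------------------------------------------------------

def method2_effects(outcome_draws: PosteriorDraws,
                    mediator_draws: Mapping[str, PosteriorDraws],
                    data: MediationDataset,
                    delta: Optional[DeltaConfig] = None) -> EffectDraws:
    """Difference-quotient estimator on posterior predictive means.

    The direct effect is the outcome contrast in the exposure with mediators
    fixed at their observed values; each indirect effect is the product of
    the mediator's response to the exposure step and the outcome's response
    to a small mediator step, averaged over subjects per draw.
    """
    out, meds = _wrap_models(outcome_draws, mediator_draws, data)
    x0, x1, dx = _exposure_arms(data, delta)
    nd = outcome_draws.n_retained
    obs = _observed_values(data, meds)
    x_obs = data.exposure.to_numpy(dtype=float)

    de = np.empty(nd)
    ie = {name: np.empty(nd) for name in meds}
    for sl in _chunks(nd):
        f_obs = None
        de[sl] = (out.mean_f(sl, x1, obs) - out.mean_f(sl, x0, obs)) / dx
        for name, mm in meds.items():
            if mm.spec.kind == "continuous":
                dm = _resolve_dm(data, name, delta)
                a_part = (mm.mean_value(sl, x1) - mm.mean_value(sl, x0)).mean(axis=1) / dx
                bumped = dict(obs)
                bumped[name] = obs[name] + dm
                if f_obs is None:
                    f_obs = out.mean_f(sl, x_obs, obs)
                b_part = (out.mean_f(sl, x_obs, bumped) - f_obs) / dm
                ie[name][sl] = a_part * b_part
            else:
                p1 = mm.probs(sl, x1)
                p0 = mm.probs(sl, x0)
                ref = mm.reference
                base = dict(obs)
                base[name] = {
                    lv: np.zeros(data.n) for lv in mm.level_order if lv != ref
                }
                eta_ref = out.eta(sl, x_obs, base)
                f_ref = expit(eta_ref) if out.kind == "logistic" else eta_ref
                acc = np.zeros(sl.stop - sl.start)
                for lv in mm.level_order:
                    if lv == ref:
                        continue
                    forced = dict(base[name])
                    forced[lv] = np.ones(data.n)
                    lifted = dict(obs)
                    lifted[name] = forced
                    eta_lv = out.eta(sl, x_obs, lifted)
                    f_lv = expit(eta_lv) if out.kind == "logistic" else eta_lv
                    acc += (((p1[lv] - p0[lv]) / dx) * (f_lv - f_ref)).mean(axis=1)
                ie[name][sl] = acc

    te = de + np.sum(list(ie.values()), axis=0) if ie else de.copy()
    _add_group_sums(ie, data.groups)
    return EffectDraws(te=te, de=de, ie=ie, method=2, groups=data.groups)


# ---------------------------------------------------------------------------
# Method 3: re-sampling
# ---------------------------------------------------------------------------

def method3_effects(outcome_draws: PosteriorDraws,
                    mediator_draws: Mapping[str, PosteriorDraws],
                    data: MediationDataset,
                    delta: Optional[DeltaConfig] = None,
                    resample_seed: int = 0,
                    n_resample: Optional[int] = None) -> EffectDraws:
    """Counterfactual re-sampling estimator.

    Per draw, the total effect contrasts predictions under the exposure step
    with mediators responding to it: continuous mediators keep each
    subject's observed value shifted by the model-predicted change, while
    binary/categorical mediators are re-sampled from their predicted
    category probabilities (common uniforms across arms).  The direct effect
    holds mediators at whole rows re-sampled with replacement from the
    empirical marginal.  Each indirect effect — and each declared group's
    joint effect — is total minus direct with only that mediator (group)
    responding.
    """
    out, meds = _wrap_models(outcome_draws, mediator_draws, data)
    x0, x1, dx = _exposure_arms(data, delta)
    nd = outcome_draws.n_retained
    n = data.n
    rng = np.random.default_rng(resample_seed)
    pool = np.arange(n)
    if n_resample is not None and n_resample < n:
        _warnings.warn(
            f"marginal resample size {n_resample} is smaller than the data "
            f"size {n}; the empirical marginal is restricted to a random "
            "subset and direct-effect draws will be noisier", stacklevel=2,
        )
        pool = rng.choice(n, size=n_resample, replace=False)
    x_obs = data.exposure.to_numpy(dtype=float)
    obs = _observed_values(data, meds)
    groups = data.groups

    te = np.empty(nd)
    de = np.empty(nd)
    ie_keys = list(meds) + list(groups)
    ie = {k: np.empty(nd) for k in ie_keys}

    for sl in _chunks(nd):
        c = sl.stop - sl.start
        # counterfactual (responding) mediator values per arm
        responding0: Dict[str, object] = {}
        responding1: Dict[str, object] = {}
        for name, mm in meds.items():
            if mm.spec.kind == "continuous":
                g_obs = mm.mean_value(sl, x_obs)
                base = obs[name][None, :]
                responding0[name] = base + (mm.mean_value(sl, x0) - g_obs)
                responding1[name] = base + (mm.mean_value(sl, x1) - g_obs)
            else:
                u = rng.random((c, n))
                responding0[name] = mm.sample_weights(sl, x0, u)
                responding1[name] = mm.sample_weights(sl, x1, u)

        # marginal draws: whole rows resampled jointly, fresh per draw; each
        # subject is paired with an independently resampled mediator row
        idx = pool[rng.integers(0, len(pool), size=(c, n))]
        marginal: Dict[str, object] = {}
        for name, mm in meds.items():
            if mm.spec.kind == "continuous":
                marginal[name] = obs[name][idx]
            else:
                marginal[name] = {lv: w[idx] for lv, w in obs[name].items()}

        def _contrast(med1, med0):
            return (out.mean_f(sl, x1, med1) - out.mean_f(sl, x0, med0)) / dx

        te[sl] = _contrast(responding1, responding0)
        de[sl] = _contrast(marginal, marginal)

        def _only(names_responding):
            med1 = dict(marginal)
            med0 = dict(marginal)
            for nm in names_responding:
                med1[nm] = responding1[nm]
                med0[nm] = responding0[nm]
            return _contrast(med1, med0) - de[sl]

        for name in meds:
            ie[name][sl] = _only([name])
        for g, members in groups.items():
            ie[g][sl] = _only(members)

    return EffectDraws(te=te, de=de, ie=ie, method=3, groups=groups)


# ---------------------------------------------------------------------------
# joint effects and summaries
# ---------------------------------------------------------------------------

def joint_effect(effects: EffectDraws, group: str) -> np.ndarray:
    """Per-draw joint indirect effect of a mediator group.

    Methods 1-2 store the per-draw sum of member effects; method 3 stores a
    block re-computation with the whole group responding to the exposure.
    Both appear under the group's label in ``effects.ie``.
    """
    if group in effects.ie:
        return effects.ie[group]
    known = sorted(k for k in effects.ie if k in effects.groups)
    raise KeyError(f"unknown mediator group {group!r}; declared groups: {known}")


@dataclass
class EffectSummary:
    """Posterior summary table of mediation effects.

    One row per mediator, group, plus the direct and total effects; columns
    hold posterior means, equal-tailed credible sets and relative effects
    (per-draw percentages of the total effect).
    """

    table: pd.DataFrame
    level: float
    method: int
    unstable_relative: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EffectSummary(method={self.method}, level={self.level})\n"
            + self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )


def _equal_tailed(v: np.ndarray, level: float):
    alpha = 1.0 - level
    lo, hi = np.quantile(v, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def summarize(effects: EffectDraws, level: float = 0.95) -> EffectSummary:
    """Posterior means, equal-tailed credible sets and relative effects.

    Relative effects are computed per draw as ``100 * effect_i / te_i`` and
    then summarized; when total-effect draws cross (or hit) zero the ratio
    draws can be extreme, so the summary is flagged as unstable.
    """
    if effects.n_retained < 100:
        raise ValueError("summaries need at least 100 retained draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    te = effects.te
    unstable = bool(np.any(te == 0) or (te.min() < 0 < te.max()))
    ok = te != 0

    def rel(v):
        r = 100.0 * v[ok] / te[ok]
        lo, hi = _equal_tailed(r, level)
        return float(r.mean()), lo, hi

    rows = []

    def add(label, role, v, with_rel=True):
        lo, hi = _equal_tailed(v, level)
        row = {
            "term": label, "role": role, "effect": float(v.mean()),
            "ci_low": lo, "ci_high": hi,
            "relative_effect": np.nan, "rel_ci_low": np.nan, "rel_ci_high": np.nan,
        }
        if with_rel:
            row["relative_effect"], row["rel_ci_low"], row["rel_ci_high"] = rel(v)
        rows.append(row)

    for name in effects.mediator_names:
        add(name, "indirect", effects.ie[name])
    for g in effects.groups:
        add(g, "joint indirect", effects.ie[g])
    add("Direct effect", "direct", effects.de)
    add("Total effect", "total", te, with_rel=False)

    table = pd.DataFrame(rows)
    table["method"] = effects.method
    return EffectSummary(table=table, level=level, method=effects.method,
                         unstable_relative=unstable)
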