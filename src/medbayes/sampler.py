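"""Bayesian GLM fitting by MCMC.

Three model families are supported, matching the needs of mediation
analysis over generalized linear models:

* **linear** — Gaussian outcome, exact conjugate Gibbs.  Coefficients get
  independent normal priors, the residual *precision* a gamma prior, and
  the sampler alternates the two closed-form full conditionals.
* **logistic** — binary outcome.  The posterior is explored with a
  random-walk Metropolis block update whose proposal covariance is the
  inverse curvature of the log posterior at its mode (scaled by the usual
  2.38^2/d factor), which mixes well for the log-concave logit posterior.
* **multinomial** — baseline-category logit for a categorical response with
  K levels: K-1 coefficient blocks against a declared reference level,
  sampled with the same mode-anchored Metropolis scheme.  With K = 2 the
  model is exactly the logistic model.

Correctness is defined by oracle equivalence: with the default near-flat
priors the posterior means approach the maximum-likelihood fits, and the
linear sampler matches the closed-form normal-gamma posterior.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, log_expit, logsumexp

from .config import ConfigError, MCMCConfig, PriorConfig

__all__ = [
    "PosteriorDraws",
    "fit_linear",
    "fit_logistic",
    "fit_multinomial",
    "posterior_predictive_mean",
    "diagnostics",
]


class RankDeficientDesign(ValueError):
    """Design matrix does not have full column rank."""


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one fitted model.

    ``coef_draws`` has one row per retained draw and one column per
    coefficient (for a multinomial model the K-1 blocks are concatenated and
    labelled ``level:column``).  ``dispersion_draws`` holds residual-variance
    draws for linear models and is ``None`` otherwise.
    """

    model_kind: str
    coef_names: List[str]
    coef_draws: np.ndarray
    dispersion_draws: Optional[np.ndarray] = None
    n_chains: int = 1
    levels: Optional[tuple] = None  # multinomial: (reference, *others)
    warnings: List[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.coef_draws.shape[0]

    def coef(self, name: str) -> np.ndarray:
        """Draw vector of one coefficient by name."""
        try:
            j = self.coef_names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient {name!r}; have {self.coef_names}") from None
        return self.coef_draws[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coef_draws, columns=self.coef_names)
        if self.dispersion_draws is not None:
            df["residual_variance"] = self.dispersion_draws
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def chain_split(self) -> List[np.ndarray]:
        """Draw matrix split into per-chain segments (chain-major storage)."""
        return np.array_split(self.coef_draws, self.n_chains, axis=0)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_design(design) -> Tuple[np.ndarray, List[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), [str(c) for c in design.columns]
    arr = np.asarray(design, dtype=float)
    if arr.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    if X.shape[0] < X.shape[1]:
        raise RankDeficientDesign(
            f"design has {X.shape[0]} rows but {X.shape[1]} columns"
        )
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[j] for j in piv[rank:])
        raise RankDeficientDesign(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _chain_seeds(mcmc: MCMCConfig) -> List[np.random.SeedSequence]:
    root = np.random.SeedSequence(mcmc.seed)
    return root.spawn(mcmc.n_chains)


# ---------------------------------------------------------------------------
# linear model: conjugate Gibbs
# ---------------------------------------------------------------------------

def fit_linear(y, design, prior: PriorConfig = PriorConfig(),
               mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Gibbs sampler for the Gaussian linear model ``y = X beta + e``.

    Full conditionals: ``beta | tau`` is multivariate normal with precision
    ``Lambda0 + tau X'X``; the residual precision ``tau | beta`` is gamma
    with shape ``a0 + n/2`` and rate ``b0 + SSR/2``.  Returns coefficient
    draws and residual-variance draws (``1/tau``).
    """
    X, names = _as_design(design)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"y has length {len(y)} but design has {n} rows")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} coefficients")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design and outcome must be free of missing/non-finite values")
    _check_rank(X, names)

    XtX = X.T @ X
    Xty = X.T @ y
    lam0 = prior.coef_precision * np.eye(p)
    lam0_m0 = prior.coef_precision * prior.coef_mean * np.ones(p)

    # initialise tau at the least-squares residual precision
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ls
    s2 = float(resid @ resid) / max(n - p, 1)
    tau_init = 1.0 / max(s2, 1e-12)

    keep = mcmc.n_retained
    all_coef = np.empty((mcmc.n_chains * keep, p))
    all_var = np.empty(mcmc.n_chains * keep)

    for c, ss in enumerate(_chain_seeds(mcmc)):
        rng = np.random.default_rng(ss)
        tau = tau_init
        beta = beta_ls.copy()
        k = 0
        for it in range(mcmc.n_iter):
            prec = lam0 + tau * XtX
            L = linalg.cholesky(prec, lower=True)
            mean = linalg.cho_solve((L, True), lam0_m0 + tau * Xty)
            z = rng.standard_normal(p)
            beta = mean + linalg.solve_triangular(L, z, lower=True, trans="T")
            r = y - X @ beta
            ssr = float(r @ r)
            tau = rng.gamma(prior.gamma_shape + 0.5 * n,
                            1.0 / (prior.gamma_rate + 0.5 * ssr))
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                all_coef[c * keep + k] = beta
                all_var[c * keep + k] = 1.0 / tau
                k += 1

    return PosteriorDraws("linear", names, all_coef, dispersion_draws=all_var,
                          n_chains=mcmc.n_chains)


# ---------------------------------------------------------------------------
# logistic and multinomial: mode-anchored random-walk Metropolis
# ---------------------------------------------------------------------------

def _newton_map(logpost_grad_hess: Callable, dim: int, max_iter: int = 100,
                tol: float = 1e-10) -> Tuple[np.ndarray, np.ndarray]:
    """Damped Newton ascent to the posterior mode; returns (mode, hessian)."""
    beta = np.zeros(dim)
    lp, g, H = logpost_grad_hess(beta)
    for _ in range(max_iter):
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-8:
            cand = beta + t * step
            lp_new, g_new, H_new = logpost_grad_hess(cand)
            if lp_new >= lp - 1e-12:
                break
            t *= 0.5
        beta, lp, g, H = cand, lp_new, g_new, H_new
        if np.max(np.abs(g)) < tol:
            break
    return beta, H


def _metropolis(logpost: Callable[[np.ndarray], float], start: np.ndarray,
                prop_chol: np.ndarray, mcmc: MCMCConfig) -> Tuple[np.ndarray, float]:
    """Block random-walk Metropolis; returns retained draws and acceptance rate."""
    dim = len(start)
    keep = mcmc.n_retained
    out = np.empty((mcmc.n_chains * keep, dim))
    accepted = 0
    total = 0
    for c, ss in enumerate(_chain_seeds(mcmc)):
        rng = np.random.default_rng(ss)
        beta = start.copy()
        lp = logpost(beta)
        k = 0
        for it in range(mcmc.n_iter):
            prop = beta + prop_chol @ rng.standard_normal(dim)
            lp_prop = logpost(prop)
            total += 1
            if np.log(rng.random()) < lp_prop - lp:
                beta, lp = prop, lp_prop
                accepted += 1
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                out[c * keep + k] = beta
                k += 1
    return out, accepted / total


def _proposal_chol(H: np.ndarray) -> np.ndarray:
    """Cholesky factor of the scaled inverse curvature (2.38^2/d * H^-1)."""
    d = H.shape[0]
    cov = np.linalg.inv(H) * (2.38 ** 2 / d)
    return np.linalg.cholesky(cov)


def fit_logistic(y, design, prior: PriorConfig = PriorConfig(),
                 mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """MCMC for the logit model ``log odds(y=1) = X beta``.

    Both outcome classes must be present.  Perfect (or quasi-perfect)
    separation leaves the posterior dominated by the weak prior; the fit
    proceeds but a warning is attached to the returned draws.
    """
    X, names = _as_design(design)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y length does not match design rows")
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError("logistic outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("logistic outcome has a single class; both 0 and 1 required")
    _check_rank(X, names)

    prec0 = prior.coef_precision
    m0 = prior.coef_mean

    def lgh(beta):
        eta = X @ beta
        lp = float(y @ eta + log_expit(-eta).sum()) \
            - 0.5 * prec0 * float(((beta - m0) ** 2).sum())
        mu = expit(eta)
        g = X.T @ (y - mu) - prec0 * (beta - m0)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + prec0 * np.eye(p)
        return lp, g, H

    mode, H = _newton_map(lgh, p)

    warn: List[str] = []
    eta_hat = X @ mode
    fitted = expit(eta_hat)
    if np.all((fitted > 0.5) == (y > 0.5)) and np.abs(eta_hat).max() > 15:
        warn.append(
            "possible perfect separation: fitted probabilities are degenerate "
            "and the posterior is dominated by the weak prior"
        )

    def logpost(beta):
        eta = X @ beta
        return float(y @ eta + log_expit(-eta).sum()) \
            - 0.5 * prec0 * float(((beta - m0) ** 2).sum())

    draws, acc = _metropolis(logpost, mode, _proposal_chol(H), mcmc)
    if acc < 0.05:
        warn.append(f"low Metropolis acceptance rate ({acc:.3f}); inspect diagnostics")
    return PosteriorDraws("logistic", names, draws, n_chains=mcmc.n_chains, warnings=warn)


def fit_multinomial(y, design, prior: PriorConfig = PriorConfig(),
                    mcmc: MCMCConfig = MCMCConfig(), reference=None) -> PosteriorDraws:
    """MCMC for the baseline-category (multinomial) logit model.

    For each non-reference level k the log odds against the reference are
    ``X beta_k``; the K-1 coefficient blocks are sampled jointly.  Draw
    columns are labelled ``level:column``.  With two levels this is exactly
    the logistic model.
    """
    X, names = _as_design(design)
    y = np.asarray(y).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y length does not match design rows")
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValueError("categorical outcome has fewer than 2 observed levels")
    if (counts == 0).any():  # np.unique never returns empties; guard for declared levels
        raise ValueError("empty category")
    levels = list(levels)
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} has no observations "
                         f"(observed levels: {levels})")
    others = [lv for lv in levels if lv != reference]
    K1 = len(others)
    dim = K1 * p

    # indicator matrix for the non-reference levels, n x (K-1)
    Z = np.column_stack([(y == lv).astype(float) for lv in others])

    prec0 = prior.coef_precision
    m0 = prior.coef_mean
    _check_rank(X, names)

    def unpack(theta):
        return theta.reshape(K1, p)

    def lgh(theta):
        B = unpack(theta)
        Eta = X @ B.T  # n x K1
        # log-normaliser includes the reference category's eta = 0
        lse = logsumexp(np.concatenate([np.zeros((n, 1)), Eta], axis=1), axis=1)
        lp = float((Z * Eta).sum() - lse.sum()) \
            - 0.5 * prec0 * float(((theta - m0) ** 2).sum())
        P = np.exp(Eta - lse[:, None])  # n x K1 category probabilities
        G = (Z - P).T @ X - prec0 * (B - m0)  # K1 x p, matching block layout
        g = G.ravel()
        H = np.empty((dim, dim))
        for a in range(K1):
            for b in range(K1):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                # negative Hessian of log-lik is +X' diag(w) X
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = X.T @ (X * w[:, None])
        H += prec0 * np.eye(dim)
        return lp, g, H

    mode, H = _newton_map(lgh, dim)

    def logpost(theta):
        B = unpack(theta)
        Eta = X @ B.T
        lse = logsumexp(np.concatenate([np.zeros((n, 1)), Eta], axis=1), axis=1)
        return float((Z * Eta).sum() - lse.sum()) \
            - 0.5 * prec0 * float(((theta - m0) ** 2).sum())

    draws, acc = _metropolis(logpost, mode, _proposal_chol(H), mcmc)
    warn: List[str] = []
    if acc < 0.05:
        warn.append(f"low Metropolis acceptance rate ({acc:.3f}); inspect diagnostics")
    coef_names = [f"{lv}:{c}" for lv in others for c in names]
    return PosteriorDraws("multinomial", coef_names, draws, n_chains=mcmc.n_chains,
                          levels=tuple([reference, *others]), warnings=warn)


# ---------------------------------------------------------------------------
# posterior predictive means
# ---------------------------------------------------------------------------

def _match_columns(draws: PosteriorDraws, new_design) -> Tuple[np.ndarray, List[str]]:
    Xnew, new_names = _as_design(new_design)
    if draws.model_kind == "multinomial":
        # per-block column names all share the same design columns
        p = Xnew.shape[1]
        block = [c.split(":", 1)[1] for c in draws.coef_names[:p]]
        expected = block
    else:
        expected = draws.coef_names
    if list(new_names) != list(expected):
        missing = [c for c in expected if c not in new_names]
        extra = [c for c in new_names if c not in expected]
        raise ValueError(
            f"design columns do not match fitted coefficients; missing {missing}, "
            f"extra/misordered {extra or new_names}"
        )
    return Xnew, new_names


def posterior_predictive_mean(draws: PosteriorDraws, new_design):
    """Posterior predictive mean function evaluated per draw and row.

    Returns a ``(n_draws, n_rows)`` array for linear (``X beta``) and
    logistic (``expit(X beta)``) models.  For a multinomial model returns a
    dict mapping each level (including the reference) to such an array of
    category probabilities; the per-row probabilities sum to one.
    """
    Xnew, _ = _match_columns(draws, new_design)
    if draws.model_kind == "linear":
        return draws.coef_draws @ Xnew.T
    if draws.model_kind == "logistic":
        return expit(draws.coef_draws @ Xnew.T)
    if draws.model_kind == "multinomial":
        ref, *others = draws.levels
        p = Xnew.shape[1]
        etas = [draws.coef_draws[:, k * p:(k + 1) * p] @ Xnew.T for k in range(len(others))]
        stack = np.stack([np.zeros_like(etas[0]), *etas])  # K x draws x rows
        stack -= logsumexp(stack, axis=0, keepdims=True)
        probs = np.exp(stack)
        return {lv: probs[i] for i, lv in enumerate((ref, *others))}
    raise ValueError(f"unknown model kind {draws.model_kind!r}")


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v = x.var()
    if v == 0 or n < 4:
        return float("nan")
    xc = x - x.mean()
    # FFT autocovariance
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum of adjacent pairs, truncated at first negative pair, made monotone
    tsum = 0.0
    prev = np.inf
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        tsum += pair
        prev = pair
    ess = n / (1.0 + 2.0 * tsum)
    return float(min(ess, n))


def mcse_mean(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean of a draw vector."""
    ess = effective_sample_size(x)
    if not np.isfinite(ess) or ess <= 0:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(ess))


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Autocorrelation at lags 1..max_lag."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return np.full(max_lag, np.nan)
    return np.array([xc[k:] @ xc[:-k] / denom for k in range(1, max_lag + 1)])


def diagnostics(draws: PosteriorDraws, max_lag: int = 50,
                ess_floor: float = 100.0) -> pd.DataFrame:
    """Per-coefficient convergence summaries.

    Columns: posterior mean and sd, MC standard error of the mean, lag-1
    autocorrelation, effective sample size, a low-ESS flag, a degenerate
    flag for constant columns, and (when several chains were run) the
    potential scale reduction factor.  Autocorrelations at lags
    1..``max_lag`` are attached as ``frame.attrs['autocorrelation']``.
    """
    if draws.n_retained < 100:
        raise ValueError("diagnostics need at least 100 retained draws")
    rows = []
    acfs = {}
    chains = draws.chain_split()
    for j, name in enumerate(draws.coef_names):
        col = draws.coef_draws[:, j]
        degenerate = bool(np.ptp(col) == 0)
        ess = float("nan") if degenerate else effective_sample_size(col)
        acf = autocorrelation(col, max_lag)
        acfs[name] = acf
        row = {
            "coefficient": name,
            "mean": col.mean(),
            "sd": col.std(ddof=1),
            "mcse_mean": float("nan") if degenerate else mcse_mean(col),
            "acf_lag1": acf[0],
            "ess": ess,
            "low_ess": bool(np.isfinite(ess) and ess < ess_floor),
            "degenerate": degenerate,
        }
        if draws.n_chains > 1:
            seg = np.array([c[:, j] for c in chains])
            row["psrf"] = _psrf(seg)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("coefficient")
    out.attrs["autocorrelation"] = pd.DataFrame(acfs, index=range(1, max_lag + 1))
    return out


def _psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction over an (m, n) chain array."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if W == 0:
        return float("nan")
    return float(np.sqrt(var_plus / W))
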