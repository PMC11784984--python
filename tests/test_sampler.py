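"""Sampler correctness against closed-form and maximum-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medbayes as mb
from medbayes.sampler import (RankDeficientDesign, autocorrelation,
                              effective_sample_size, fit_linear, fit_logistic,
                              fit_multinomial, posterior_predictive_mean)


def _design(x):
    n = len(x)
    return pd.DataFrame({"Intercept": np.ones(n), "x": x})


def conjugate_posterior_mean(y, X, prior):
    """Closed-form normal-gamma posterior mean of the coefficients (the
    weak prior precision is treated as scale-free, which it is to O(1e-6))."""
    lam = prior.coef_precision * np.eye(X.shape[1])
    # posterior mean of beta: (X'X + lam*s2)^-1 X'y with s2 the residual scale;
    # with precision 1e-6 the ridge term is negligible at any plausible s2
    return np.linalg.solve(X.T @ X + lam, X.T @ y)


class TestLinear:
    def test_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.standard_normal(n)
        y = 2.0 + 3.0 * x + 0.1 * rng.standard_normal(n)
        X = _design(x)
        prior = mb.PriorConfig()
        draws = fit_linear(y, X, prior, mb.MCMCConfig(seed=1))
        oracle = conjugate_posterior_mean(y, X.to_numpy(), prior)
        assert abs(draws.coef("x").mean() - oracle[1]) < 0.05
        assert abs(draws.coef("Intercept").mean() - oracle[0]) < 0.05

    def test_constant_outcome_recovers_no_signal(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(300)
        y = np.full(300, 5.0)
        draws = fit_linear(y, _design(x), mcmc=mb.MCMCConfig(seed=2))
        assert abs(draws.coef("x").mean()) < 0.01
        assert abs(draws.coef("Intercept").mean() - 5.0) < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        y = 1 + x + rng.standard_normal(100)
        cfg = mb.MCMCConfig(n_iter=600, burn_in=100, seed=99)
        d1 = fit_linear(y, _design(x), mcmc=cfg)
        d2 = fit_linear(y, _design(x), mcmc=cfg)
        np.testing.assert_array_equal(d1.coef_draws, d2.coef_draws)
        np.testing.assert_array_equal(d1.dispersion_draws, d2.dispersion_draws)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"Intercept": 1.0, "x": x, "x_copy": x})
        with pytest.raises(RankDeficientDesign, match="x_copy|x"):
            fit_linear(rng.standard_normal(50), X)

    def test_bad_mcmc_config_rejected(self):
        with pytest.raises(mb.ConfigError):
            mb.MCMCConfig(n_iter=100, burn_in=100)

    def test_posterior_variance_matches_conjugate(self):
        # empirical coefficient variance vs the t-marginal of the conjugate
        # normal-gamma posterior, within Monte-Carlo error
        rng = np.random.default_rng(7)
        n = 400
        x = rng.standard_normal(n)
        y = 1.0 + 2.0 * x + rng.standard_normal(n)
        X = _design(x).to_numpy()
        prior = mb.PriorConfig()
        draws = fit_linear(y, _design(x), prior, mb.MCMCConfig(seed=3))
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bhat
        a_n = prior.gamma_shape + n / 2
        b_n = prior.gamma_rate + 0.5 * float(resid @ resid + 0.0)
        # marginal coefficient variance: E[sigma^2] * (X'X)^-1
        var_oracle = (b_n / (a_n - 1)) * np.linalg.inv(X.T @ X)
        for j in (0, 1):
            emp = draws.coef_draws[:, j].var(ddof=1)
            mc_se = emp * np.sqrt(2.0 / effective_sample_size(draws.coef_draws[:, j]))
            assert abs(emp - var_oracle[j, j]) < 4 * mc_se + 1e-8


class TestLogistic:
    def test_recovers_ml_fit(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(1 - 2 * x))
        y = rng.binomial(1, p).astype(float)
        draws = fit_logistic(y, _design(x), mcmc=mb.MCMCConfig(seed=4))
        for j, truth in enumerate((-1.0, 2.0)):
            col = draws.coef_draws[:, j]
            assert abs(col.mean() - truth) < 3 * col.std()

    def test_single_class_errors(self):
        x = np.linspace(-1, 1, 50)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(50), _design(x))

    def test_separation_warns_in_draws(self):
        x = np.linspace(-2, 2, 80)
        y = (x > 0).astype(float)
        draws = fit_logistic(y, _design(x), mcmc=mb.MCMCConfig(n_iter=600, burn_in=100, seed=5))
        assert any("separation" in w for w in draws.warnings)

    def test_null_slope_interval_coverage(self):
        # x unrelated to y: the 95% credible set for the slope should cover 0
        # in roughly 95% of replicates (binomial slack at 30 reps)
        covered = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            x = rng.standard_normal(400)
            y = rng.binomial(1, 0.5, 400).astype(float)
            d = fit_logistic(y, _design(x),
                             mcmc=mb.MCMCConfig(n_iter=1600, burn_in=300, seed=r))
            lo, hi = np.quantile(d.coef("x"), [0.025, 0.975])
            covered += (lo <= 0.0 <= hi)
        assert covered >= 0.80 * reps


class TestMultinomial:
    def test_no_association_slopes_near_zero(self):
        rng = np.random.default_rng(9)
        n = 1500
        x = rng.standard_normal(n)
        y = rng.integers(0, 3, n)
        draws = fit_multinomial(y, _design(x), mcmc=mb.MCMCConfig(seed=6), reference=0)
        for lv in (1, 2):
            col = draws.coef(f"{lv}:x")
            assert abs(col.mean()) < 3 * col.std()

    def test_recovers_baseline_logit_truth(self):
        rng = np.random.default_rng(10)
        n = 3000
        x = rng.binomial(1, 0.4, n).astype(float)
        eta = np.column_stack([np.zeros(n), 0.5 + 1.0 * x, 1.5 - 1.0 * x])
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        y = (u[:, None] >= p.cumsum(axis=1)).sum(axis=1)
        draws = fit_multinomial(y, _design(x), mcmc=mb.MCMCConfig(seed=7), reference=0)
        truth = {"1:Intercept": 0.5, "1:x": 1.0, "2:Intercept": 1.5, "2:x": -1.0}
        for name, val in truth.items():
            col = draws.coef(name)
            assert abs(col.mean() - val) < 3 * col.std(), name

    def test_two_level_reduction_matches_logistic(self):
        rng = np.random.default_rng(11)
        n = 800
        x = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.3 - 0.8 * x))).astype(float)
        cfg = mb.MCMCConfig(n_iter=3000, burn_in=500, seed=8)
        d_logit = fit_logistic(y, _design(x), mcmc=cfg)
        d_multi = fit_multinomial(y.astype(int), _design(x), mcmc=cfg, reference=0)
        assert d_multi.levels == (0, 1)
        for a, b in zip(("Intercept", "x"), ("1:Intercept", "1:x")):
            ks = stats.ks_2samp(d_logit.coef(a), d_multi.coef(b))
            assert ks.pvalue > 0.01

    def test_missing_reference_level_errors(self):
        y = np.array([1, 2, 1, 2, 1, 2] * 10)
        X = _design(np.linspace(0, 1, 60))
        with pytest.raises(ValueError, match="reference"):
            fit_multinomial(y, X, reference=0)


class TestPredictiveMean:
    def test_linear_arithmetic(self):
        d = mb.PosteriorDraws("linear", ["Intercept", "x"], np.array([[1.0, 2.0]]))
        out = posterior_predictive_mean(d, pd.DataFrame({"Intercept": [1.0], "x": [3.0]}))
        assert out.shape == (1, 1) and out[0, 0] == 7.0

    def test_logistic_symmetry_at_zero(self):
        d = mb.PosteriorDraws("logistic", ["Intercept", "x"], np.zeros((5, 2)))
        out = posterior_predictive_mean(d, pd.DataFrame({"Intercept": [1.0], "x": [2.5]}))
        assert np.allclose(out, 0.5)

    def test_multinomial_probabilities_normalized(self):
        rng = np.random.default_rng(12)
        d = mb.PosteriorDraws("multinomial",
                              ["a:Intercept", "a:x", "b:Intercept", "b:x"],
                              rng.normal(size=(40, 4)), levels=("ref", "a", "b"))
        X = pd.DataFrame({"Intercept": np.ones(7), "x": rng.normal(size=7)})
        probs = posterior_predictive_mean(d, X)
        total = sum(probs.values())
        assert np.abs(total - 1.0).max() < 1e-12
        assert all((p >= 0).all() for p in probs.values())

    def test_column_mismatch_named(self):
        d = mb.PosteriorDraws("linear", ["Intercept", "x"], np.ones((3, 2)))
        with pytest.raises(ValueError, match="missing.*'x'"):
            posterior_predictive_mean(d, pd.DataFrame({"Intercept": [1.0], "z": [1.0]}))


class TestDiagnostics:
    def test_independent_draws_full_ess(self):
        rng = np.random.default_rng(13)
        d = mb.PosteriorDraws("linear", ["a"], rng.standard_normal((4000, 1)))
        rep = mb.diagnostics(d)
        assert abs(rep.loc["a", "acf_lag1"]) < 0.05
        assert rep.loc["a", "ess"] > 3000

    def test_ar1_ess_matches_analytic(self):
        rho = 0.9
        rng = np.random.default_rng(14)
        n = 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        ess = effective_sample_size(x)
        analytic = n * (1 - rho) / (1 + rho)
        assert abs(ess - analytic) < 0.30 * analytic

    def test_constant_column_flagged_degenerate(self):
        d = mb.PosteriorDraws("linear", ["a", "b"],
                              np.column_stack([np.ones(500), np.random.default_rng(1).normal(size=500)]))
        rep = mb.diagnostics(d)
        assert bool(rep.loc["a", "degenerate"])
        assert not bool(rep.loc["b", "degenerate"])

    def test_ess_cross_checked_against_arviz(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            import arviz as az
        rho = 0.8
        rng = np.random.default_rng(20)
        n = 10000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()
        ours = effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert abs(ours - theirs) < 0.3 * theirs

    def test_multichain_psrf_near_one_for_stationary_chains(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(200)
        y = 1 + 2 * x + rng.standard_normal(200)
        draws = fit_linear(y, _design(x),
                           mcmc=mb.MCMCConfig(n_iter=800, burn_in=200, n_chains=3, seed=22))
        assert draws.n_retained == 3 * 600
        rep = mb.diagnostics(draws)
        assert "psrf" in rep.columns
        assert np.all(rep["psrf"] < 1.05)

    def test_autocorrelation_lags_shape(self):
        x = np.random.default_rng(2).normal(size=1000)
        acf = autocorrelation(x, max_lag=50)
        assert acf.shape == (50,)
        assert np.all(np.abs(acf) < 0.15)


class TestFlatPriorLimit:
    """With near-flat priors and moderate n the posterior means track the MLE."""

    def test_linear_tracks_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(15)
        n = 600
        X = pd.DataFrame({"Intercept": np.ones(n), "x1": rng.standard_normal(n),
                          "x2": rng.standard_normal(n)})
        y = 1 + 0.5 * X["x1"] - 2 * X["x2"] + rng.standard_normal(n)
        mle = sm.OLS(y, X).fit().params.to_numpy()
        draws = fit_linear(y, X, mcmc=mb.MCMCConfig(seed=9))
        post = draws.coef_draws.mean(axis=0)
        assert np.all(np.abs(post - mle) < 0.02 * np.abs(mle) + 0.02)

    def test_logistic_tracks_ml(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(16)
        n = 1500
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.standard_normal(n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.9 * X["x"])))).astype(float)
        mle = sm.Logit(y, X).fit(disp=0).params.to_numpy()
        draws = fit_logistic(y, X, mcmc=mb.MCMCConfig(seed=10))
        post = draws.coef_draws.mean(axis=0)
        assert np.all(np.abs(post - mle) < 0.02 * np.abs(mle) + 0.02)

    def test_multinomial_tracks_ml(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(17)
        n = 1500
        x = rng.standard_normal(n)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        eta = np.column_stack([np.zeros(n), -0.2 + 0.7 * x, 0.4 - 0.5 * x])
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        y = (rng.random(n)[:, None] >= p.cumsum(axis=1)).sum(axis=1)
        mle = sm.MNLogit(y, X).fit(disp=0).params.to_numpy().T.ravel()
        draws = fit_multinomial(y, X, mcmc=mb.MCMCConfig(seed=11), reference=0)
        post = draws.coef_draws.mean(axis=0)
        assert np.all(np.abs(post - mle) < 0.02 * np.abs(mle) + 0.02)
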