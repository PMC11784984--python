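# medbayes — Bayesian mediation analysis over generalized linear models

`medbayes` decomposes the effect of an exposure X on an outcome Y into a
direct component and indirect components transmitted through mediators
M₁,…,M_J, using posterior draws from Bayesian generalized linear models.  It
is aimed at epidemiologists and biostatisticians studying, e.g., health
disparities: a binary exposure such as race, a continuous outcome such as
diagnostic age, and a mix of categorical mediators (insurance, marital
status) and continuous ones (neighborhood walkability measures).

## The model and the three estimators

The outcome and each mediator get a Bayesian GLM, e.g. in the all-linear
single-mediator case

    Y = i₀ + cX + bM + e₁,      M = i₁ + aX + e₂,

with independent normal priors on the coefficients (mean 0, precision 10⁻⁶
by default) and a gamma(shape 1, rate 0.1) prior on each residual precision.
Linear models are sampled with an exact conjugate Gibbs sampler; logistic
and baseline-category multinomial-logit models (a categorical mediator with
K levels is modelled through K−1 log odds against a reference level) use a
mode-anchored random-walk Metropolis sampler.  The default run keeps 10,000
of 11,000 single-chain iterations.

Effects are defined as rates of change of E[Y] in X: the **total effect**
(TE) lets mediators respond to X, the **direct effect** (DE) holds them at
their marginal distribution, and each **indirect effect** (IE) is the part
of TE transmitted through one mediator (or a declared mediator group).
For a binary exposure the rate is the full 0→1 contrast.  Three estimators
turn posterior draws into per-draw effect values:

1. **Functions of coefficients** — analytic: per draw, IE = a·b for a
   continuous mediator, IE = Σₖ bₖ·ΔPₖ/Δx for a categorical one, DE = c;
   under a logistic outcome the same functions are weighted by the mean
   derivative of the inverse logit at the observed linear predictor.
2. **Product of partial differences** — derivative-free: difference
   quotients of posterior predictive means with steps Δx, Δm resolved as
   min(0.01, range/100) for continuous variables.
3. **Re-sampling** — counterfactual: TE contrasts predictions with all
   mediators responding to the exposure shift; DE holds mediators at whole
   rows re-sampled from their empirical marginal; IE = TE − DE with only the
   mediator (or group) of interest responding.

Per-draw effects are summarized into posterior means, 95% equal-tailed
credible sets and **relative effects** (per-draw percentages of the total
effect).  Candidate mediators can first be screened by the two-condition
rule: association with the outcome (adjusted GLM Wald test) and a
distribution difference across exposure groups (chi-square / ANOVA), both at
the 0.1 level, with substantively important variables forced past the tests.

## Worked example

`examples/01_fit_and_decompose.py` generates a registry-like synthetic
cohort (n = 2,275, binary exposure at 30.6% prevalence, age-like outcome,
insurance-like and marital-like categorical mediators, two correlated
walkability-like continuous mediators with a declared group), fits all
models, and runs the re-sampling estimator:

```
ground truth: TE=-5.127  DE=-4.000
EffectSummary(method=3, level=0.95)
          term           role  effect  ci_low  ci_high  relative_effect  rel_ci_low  rel_ci_high  method
     insurance       indirect -0.5804   -1.07   -0.111            10.86       2.062         20.5       3
       marital       indirect -0.2835 -0.4988 -0.08481            5.303       1.605          9.5       3
street_density       indirect -0.1977 -0.5759   0.1819            3.704      -3.426        10.95       3
    node_ratio       indirect -0.2802 -0.6423  0.06345            5.235      -1.181        12.26       3
   walkability joint indirect -0.4779   -0.85  -0.1095            8.939       2.053         16.3       3
 Direct effect         direct  -4.049  -5.272   -2.882             74.9        61.5        87.43       3
  Total effect          total  -5.391  -6.455   -4.356              NaN         NaN          NaN       3
```

Read it like a disparity decomposition: exposed subjects' expected outcome
is 5.39 units lower in total (credible set excluding 0); about 10.9% of that
gap is transmitted through the insurance mediator (its credible set also
excludes 0), while the joint walkability group carries 8.9%.  All intervals
cover the generating truth shown above.  The other examples compare the
three estimators per draw (`02`), demonstrate screening decisions (`03`),
and run the file-in/report-out pipeline (`04`).

A thin CLI wraps the same pipeline:

```bash
medbayes simulate --template registry --n 2000 --seed 1 --out cohort.csv
medbayes all --config run.yaml --seed 1 --out results/
```

`results/` then contains `effects.csv`/`effects.json`, `screening.csv`,
per-model posterior draws, `diagnostics.txt` (ESS, autocorrelation, MC
errors) and a timestamped `run.log`.

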