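# Methods

## Effect definitions

Let f(Y|X,M) be the posterior predictive mean of the outcome model and
g(M|X) that of a mediator model.  Effects are rates of change of the
expected outcome in the exposure, averaged over the observed subjects'
covariate values at every posterior draw (population-level interpretation):

* **Total effect** — change in f when X shifts and every mediator responds
  to the shift through its model.
* **Direct effect** — change in f when X shifts while mediators are held at
  draws from their marginal distribution.
* **Indirect effect of Mⱼ** — TE − DE computed with only Mⱼ (or only the
  members of a declared group, jointly) responding to the shift.

For a **binary exposure** the shift is the full 0 → 1 contrast (Δx = 1):
the infinitesimal rate of change has no meaning between two categories, and
the reported numbers are then interpretable as group contrasts (e.g. years
of diagnostic age).  For a **continuous exposure** the step defaults to
min(0.01, range(X)/100); the mediator step in method 2 uses the analogous
min(0.01, range(M)/100) per mediator.  Both can be overridden in
`DeltaConfig`.

## Models and priors

* Coefficients: independent normal priors, mean 0, precision 10⁻⁶
  (effectively non-informative at the data scales used here).
* Residual precisions of linear models: gamma(shape 1, rate 0.1).  The
  gamma prior is placed on the **precision**, the convention of
  Gibbs-sampling toolchains; "variance parameter" summaries are reported as
  1/τ draws.
* Linear models: exact conjugate Gibbs (normal full conditional for the
  coefficient block, gamma for the precision).  Initialization at the
  least-squares solution; the chain is effectively stationary immediately,
  but the default burn-in is still discarded.
* Logistic and baseline-category multinomial-logit models: damped-Newton
  ascent to the posterior mode, then block random-walk Metropolis with
  proposal covariance (2.38²/d)·H⁻¹ where H is the negative log-posterior
  Hessian at the mode.  The logit posterior is log-concave, so the
  mode-anchored scale mixes well; acceptance below 5% attaches a warning.
  A categorical response with K levels contributes K−1 coefficient blocks
  against a declared reference level; K = 2 is exactly the logistic model.
* Defaults: one chain, 11,000 iterations, 1,000 burn-in, no thinning
  (10,000 retained).  Multiple chains are supported (`n_chains`), in which
  case diagnostics add the potential scale reduction factor.
* Missing data: complete-case deletion at dataset construction, with the
  dropped-row count logged.

Correctness is defined by oracle equivalence, not by a particular sampler:
the linear sampler must match the closed-form normal–gamma posterior, and
with near-flat priors all three model kinds must approach their
maximum-likelihood fits (both are tested).

## Estimators

**Method 1 (functions of coefficients).**  Per retained draw i: linear
outcome with continuous mediator, IEᵢ = aᵢ·bᵢ and DEᵢ = cᵢ; categorical
mediator, IEᵢ = Σₖ bₖ,ᵢ·[Pₖ(x+Δx) − Pₖ(x)]/Δx averaged over subjects, with
Pₖ the multinomial inverse link.  A logistic outcome multiplies these
coefficient functions by w̄ᵢ, the subject-average of expit(η)(1−expit(η)) at
the draw's observed linear predictor — i.e. the error term inside the
predictive expression is set to its mean (0) and the printed weight is the
derivative of the inverse logit.  TE = DE + ΣIE by construction, so
additivity is exact per draw.

**Method 2 (product of partial differences).**  DE is the subject-averaged
difference quotient of f in X at observed mediator values; IEⱼ is the
product of (a) the quotient of gⱼ in X and (b) the quotient of f in Mⱼ.
Categorical mediators contribute Σₖ ΔPₖ/Δx times the outcome contrast
between level k and the reference, per subject.  For linear models all
quotients are exact, so methods 1 and 2 coincide per draw to floating-point
error (tested at 1e−8).

**Method 3 (re-sampling).**  Counterfactual mediator values under an
exposure arm are built as follows: a continuous mediator keeps each
subject's observed value shifted by the model-predicted change,
m + g(x_arm) − g(x_obs), preserving residual heterogeneity; binary and
categorical mediators are *sampled* from their predicted category
probabilities, using common uniform variates across arms (and across the
TE/IE evaluations) to cancel sampling noise from the contrasts.  Marginal
draws for the DE resample whole mediator rows with replacement — jointly, so
inter-mediator correlation is preserved — fresh at every MCMC draw and
seeded independently of the MCMC seed.  Group (joint) effects are
re-computed with the whole group responding as a block; for methods 1–2 the
group entry is the per-draw sum of its members (both views are exposed, as
additivity makes them identical in the linear case).

**Estimand caveat (logistic outcome).**  Method 1 evaluates its weight w̄ at
the observed joint distribution of (X, M); method 3's direct effect averages
the same curvature over the product of marginals.  The two indirect effects
therefore differ by a term of order c·(E_joint[w] − E_marginal[w]), which
vanishes when the direct pathway is absent or the outcome is linear.  The
logistic validation fixture is built with no direct pathway so that the two
estimators share one estimand; with a direct effect present, differences of
a few per mille in the IE are expected and are a property of the estimands,
not an implementation error.

**Summaries.**  Posterior means and equal-tailed quantile credible sets
(not HPD — matching standard MCMC-workflow reporting; linear-interpolation
quantiles).  Relative effects are computed **per draw** as 100·IEᵢ/TEᵢ and
100·DEᵢ/TEᵢ, then summarized — so the mean relative effects of DE and the
group-level IEs sum to exactly 100% whenever per-draw additivity holds.
If any TE draw is zero or the TE draws change sign, the ratio draws can be
extreme and the summary is flagged `unstable_relative` (zero-TE draws are
excluded from the ratio).

## Screening

Condition 1: Wald test of the candidate's block in a GLM of the outcome on
candidate + adjusters (identity-link Gaussian for continuous outcomes,
logit for binary; categorical candidates tested jointly on their K−1
dummies).  Adjusters default to the exposure plus the other candidates'
blocks, both configurable.  Condition 2: uncorrected chi-square for
categorical candidates, one-way ANOVA for continuous.  Both p-values must
fall below α = 0.1 unless the candidate is forced.  Expected cell counts
below 5 raise a warning rather than switching to an exact test, matching
classic contingency-table practice at these sample sizes.  No multiplicity
correction: these are pre-screens, not formal mediation tests.

## Synthetic data generator

The generator emulates the structure of a registry disparity cohort:
n = 2,275 with binary exposure prevalence 696/2275 ≈ 0.306 by default; a
continuous age-like outcome (intercept 62, residual sd 12); a 3-level
insurance-like and a 4-level marital-like categorical mediator driven by
baseline-category logits in the exposure; and two continuous
environment-like mediators with exposure-dependent means and residual
correlation 0.5, sharing a group label so joint-effect logic is exercised.
A logistic-outcome template (continuous exposure, single continuous
mediator, no direct pathway — see the estimand caveat) exercises the logit
branch.  `true_effects` returns exact ground truth for linear outcomes
(IE = a·b; categorical IE = Σₖ bₖ·[Pₖ(1) − Pₖ(0)]); nonlinear outcomes are
refused and left to Monte-Carlo oracles.

What the generator does **not** emulate: real registries' missingness,
measurement error, confounding of the mediator–outcome relation, nonlinear
dose–response, and the exact joint distribution of a real cohort's
covariates.  Passing tests therefore demonstrate estimator correctness under
the generating models, not robustness to model misspecification.

## Numerical choices and problem sizes

* Draw-chunked evaluation (256 draws per block) keeps the predictive-mean
  arrays at ~chunk × n doubles regardless of the retained draw count.
* Rank-deficient designs are rejected with the collinear columns named
  (pivoted QR); perfectly separated logistic data fit under the weak prior
  but carry a warning.
* ESS uses Geyer's initial monotone positive-sequence estimator; MC standard
  errors of posterior means are sd/√ESS.  Agreement checks between two
  estimators use 3·√(MCSE₁² + MCSE₂²); checks of one estimate against a
  known truth use 3 posterior SDs (a posterior mean is ~1 posterior SD from
  the truth under correct coverage, far above its MC-SE).
* Validation studies run at n = 500–3,000 with 2,000–10,000 retained draws
  and 100–200 replicates for the coverage/calibration studies; these sizes
  give Monte-Carlo error comfortably below the tested tolerances.

## Known limitations

* No exposure–mediator interactions, mediator–mediator causal ordering, or
  sensitivity analysis for unmeasured confounding.
* No survival outcomes and no multilevel/hierarchical models.
* Method 1 supports linear and logistic outcome models only; other outcome
  families should use methods 2–3.
* Samplers are Metropolis/Gibbs, not HMC; heavy-tailed or high-dimensional
  posteriors may need longer runs (watch the ESS column in diagnostics).
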