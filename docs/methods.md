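# Methods

## Cohort model

`ponvbart.cohort` loads a row-level surgical cohort from CSV into
validated `SubjectRecord` objects. Column names and cannabis-use value
spellings are remappable through a `ColumnDialect`; malformed rows are
rejected individually with the offending field named, never silently
coerced.

Inclusion filters (`apply_inclusion_filters`) mirror a retrospective
PONV study design: adults (age ≥ 18), ASA physical status ≤ 3, surgical
duration ≥ 30 minutes, general anesthesia, recovery in the PACU, and
exclusion of obstetric and cardiac cases. The exclusion tally counts a
subject under every criterion it fails.

Derived quantities:

- **Apfel simplified risk score** (0–4): female sex + history of PONV or
  motion sickness + non-smoker + postoperative opioids in the PACU.
- **Exposure indicators**: nitrous oxide if the N₂O time fraction
  exceeds 0.05; potent volatile agent if the MAC-weighted time fraction
  exceeds 0.15.
- **Feature matrix**: 13 columns — age, female, ASA 2/3 dummies,
  cannabis current/daily dummies (none = reference), smoker, prior
  PONV/motion sickness, PACU opioids, N₂O, volatile agent,
  log(duration), prophylactic antiemetic count.

`summarize_cohort` produces Table-1-style descriptives per cannabis-use
level; `summarize_aggregate` computes the same statistics from published
aggregate counts (a small JSON fixture of the source study's stratum
sizes and PONV counts ships with the package).

## Probit BART

The outcome model is
`P(y = 1 | x) = Φ(offset + Σ_{j=1..m} g(x; T_j, M_j))`,
a sum of `m` regression trees under the BART prior.

**Latent augmentation (Albert–Chib).** Each sweep refreshes latent
`z_i ~ N(f(x_i), 1)` truncated to `z_i > 0` when `y_i = 1` and
`z_i < 0` otherwise. Truncated-normal draws use the log-space inverse-CDF
form `t = −ndtri_exp(log U + log Φ(μ))` (and its mirror), which stays
exact for means many standard deviations from the truncation point.

**Backfitting.** For each tree in turn, its fit is subtracted from the
running total to form partial residuals `r`; one Metropolis–Hastings
structural move is proposed, then all leaf values are redrawn from their
conjugate conditional `μ | r ~ N(σ_μ² s / (1 + n σ_μ²), σ_μ² / (1 + n σ_μ²))`
with `s = Σ r_i` over the leaf.

**Priors.** Split probability at depth `d` is `α (1 + d)^{−β}` with
`α = 0.95`, `β = 2` (the standard BART default, favouring shallow
trees). Split variables are uniform over usable covariates and cutpoints
uniform over a per-covariate grid (exact midpoints when a covariate has
at most `n_cutpoints = 100` distinct values, else a uniform interior
grid). Leaf values are `N(0, σ_μ²)` with `σ_μ = 3 / (k √m)`, `k = 2`,
so the prior on `f` concentrates `Φ(f)` inside (Φ(−3), Φ(3)). Because
the latent variance is fixed at 1, leaf values integrate out in closed
form; MH ratios use the integrated marginal, so structural moves never
depend on current leaf values.

**Moves.** Grow / prune / change / swap with probabilities
0.25 / 0.25 / 0.40 / 0.10. Grow–prune acceptance includes the tree-prior
ratio and the proposal asymmetry (number of growable leaves vs prunable
internal nodes); change and swap are symmetric, so only the integrated
marginal ratio enters. Any proposal that creates an empty leaf has zero
posterior mass and is rejected outright.

**Defaults.** `m = 50` trees, `ndpost = 1000` retained draws after
`nskip = 100` burn-in, offset `Φ⁻¹(ȳ)`. Latent predictions are clipped
to ±8.2 before `Φ` so probabilities stay strictly inside (0, 1) in
double precision. The tie convention is “≤ goes left”. The sampler was
validated against exact enumeration of a two-state tree posterior, an
analytic intercept-only probit posterior (numerical integration), and a
step-signal recovery problem; those checks live in the test suite.

## Causal estimand and g-computation

The estimand is the **sample average treatment effect** of cannabis-use
level on PONV: for each posterior draw `s` and each level `a`, the
cohort-mean counterfactual risk `p̄_a^(s) = n⁻¹ Σ_i Φ(f^(s)(x_i, a))`
with every subject's other covariates held at their observed values.
Then `RR^(s) = p̄_daily^(s) / p̄_none^(s)` (similarly current vs none)
and `RD^(s)` the difference. Posterior summaries are means,
equal-tailed 95% credible intervals, and the strict exceedance
probability `P(RR > 1)`. Stratified results condition on the subject's
*factual* Apfel score (the grid never alters Apfel components), with the
pooled result the subject-weighted combination. Identification requires
the usual no-unmeasured-confounding and positivity assumptions — the
method adjusts only for the covariates in the feature matrix.

## Propensity validation arm

A Bayesian logistic model estimates the propensity of *any* cannabis use
from the non-treatment covariates; the posterior-mean propensity (as a
percentage, entering per 1%) then joins the covariates in a Bayesian
logistic outcome model. Both models use weakly-informative independent
normal priors `N(0, 2.5 / sd(x))` per coefficient (scale 10 for the
intercept) and are sampled by independence Metropolis–Hastings from a
Laplace approximation at the penalized mode (BFGS + Cholesky); ≥ 2
chains with split-R̂ < 1.05 required, and an acceptance-rate/ separation
warning otherwise. Outputs: a 16-row odds-ratio table in the
conventional layout (reference rows included) and a logistic
g-computation sATE for direct comparison with the BART arm.

## Synthetic cohort generator

`ponvbart.simulate` draws covariates from marginals matched to a large
surgical cohort, assigns cannabis-use level from a confounded
multinomial-logit model (daily users more often male, smokers, with
prior PONV, PACU opioids, and ASA 3), and draws PONV from a probit
model — so the fitted model class contains the truth and estimator bias
is attributable to the estimator, not model misspecification. Calibrated
constants are frozen in code: assignment intercepts give prevalences
≈ 90 / 7.2 / 2.7 % (none/current/daily); outcome intercept gives
≈ 17.3 % incidence in non-users; treatment coefficients 0.049 (current)
and 0.135 (daily) on the latent scale give true sATE RRs of ≈ 1.07 and
≈ 1.20. `true_sate` is a brute-force oracle: it draws a large fresh
covariate sample from an independent seed stream and averages the exact
probit probabilities under each forced level, reporting delta-method
Monte-Carlo standard errors. `null_config` zeroes both treatment
coefficients for calibration studies (its RR is exactly 1 by
construction). Fixtures round-trip byte-identically through
`write_fixture` / `load_cohort`.

## Pipeline and reproducibility

`run_pipeline` takes a config mapping or YAML file: input (simulate or
CSV), model settings, validation settings, optional replication input,
output directory. A single top-level seed deterministically derives one
sub-seed per stage (simulation, BART, propensity, outcome logistic,
replicate) via `numpy.random.SeedSequence`, all below 2³¹; the manifest
records them plus package/numpy versions, so a manifest reproduces a run
bit-identically on the same platform. Replicate mode refits the entire
analysis on an independent cohort and reports both pooled estimates side
by side.

## Study-condition choices and limitations

- Default synthetic study sizes (n = 8000 in `scripts/acceptance.py`,
  n = 2000–4000 in the test suite) trade Monte-Carlo precision against
  single-CPU runtime. With ~2.7 % daily-use prevalence, a cohort of
  8000 has only ~200 daily users, so single-cohort RR estimates carry
  sampling noise of roughly ±0.15–0.2; calibration and recovery claims
  are therefore tested across replicated cohorts, not single draws.
- BART's shrinkage priors pull small-stratum effects toward zero; at
  n = 4000 the daily-vs-none RR shows a small negative bias (on the
  order of 0.1) that shrinks with cohort size. This is a property of
  the prior, not a sampler defect, and is documented by the effect-
  recovery test.
- The logistic validation arm is a parametric approximation; agreement
  with the BART arm (typically within 0.1 in RR) is a consistency
  check, not an independent identification strategy.
- All causal claims are conditional on no unmeasured confounding;
  neither arm can detect violations of it.
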