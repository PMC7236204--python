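# ponvbart

Bayesian causal analysis of cannabis use and postoperative nausea and
vomiting (PONV), built around a from-scratch probit Bayesian Additive
Regression Trees (BART) sampler.

Retrospective surgical cohorts show a modestly higher PONV incidence in
cannabis users, but use is confounded: daily users are more often male,
smokers, and have different anesthetic exposures, all of which shift PONV
risk in their own right. `ponvbart` estimates the *sample average
treatment effect* (sATE) of cannabis use on PONV by g-computation over a
flexible Bayesian outcome model:

1. **Cohort model** — load a row-level surgical cohort from CSV, apply
   the study's inclusion filters, derive exposure indicators and the
   Apfel simplified risk score, and produce Table-1-style descriptives
   (`ponvbart.cohort`).
2. **Probit BART** — a full MCMC sampler for
   `P(PONV | x) = Φ(Σ_j g(x; T_j))`, with Albert–Chib latent-variable
   augmentation, Bayesian backfitting, and grow/prune/change/swap
   Metropolis–Hastings tree moves (`ponvbart.bart`).
3. **Causal g-computation** — counterfactually force every subject to
   each cannabis-use level, push all three design matrices through the
   posterior, and report posterior RR and risk difference with credible
   intervals and exceedance probabilities, pooled and by Apfel score
   (`ponvbart.gcomp`).
4. **Propensity validation arm** — an independent Bayesian logistic
   pathway (logistic propensity model for any cannabis use, then a
   propensity-adjusted logistic outcome model) that produces a
   conventional odds-ratio table and a logistic sATE to cross-check the
   BART estimate (`ponvbart.propensity`).
5. **Synthetic cohorts** — a confounded cohort generator with a
   brute-force ground-truth oracle, used throughout the test suite and
   for study-design calibration (`ponvbart.simulate`).
6. **Pipeline & CLI** — one config drives the whole study end to end,
   including an independent-cohort replication, writing all artifacts
   plus a seed/version manifest (`ponvbart.pipeline`, `ponvbart` CLI).

## Worked example

```python
from ponvbart.bart import BartConfig, fit_pbart
from ponvbart.cohort import build_feature_matrix
from ponvbart.gcomp import build_counterfactual_grid, sate
from ponvbart.pipeline import format_rr
from ponvbart.simulate import SimConfig, simulate_cohort

records, truth = simulate_cohort(SimConfig(n=4000, seed=31))
features = build_feature_matrix(records)
fit = fit_pbart(features.X, features.y,
                BartConfig(m=50, ndpost=500, nskip=100, seed=1))
for r in sate(fit, build_counterfactual_grid(features)):
    if r.stratum == "pooled":
        print(r.contrast, format_rr(r.rr_mean, r.rr_ci_low,
                                    r.rr_ci_high, r.prob_rr_gt_1))
print("true daily RR:", truth.pooled["daily_vs_none"]["rr"])
```

prints

```
current_vs_none 1.01 (95% CI 0.76–1.29, posterior probability RR > 1 = 53.6%)
daily_vs_none 1.21 (95% CI 0.81–1.61, posterior probability RR > 1 = 81.8%)
true daily RR: 1.2003...
```

To analyze a real cohort, point the pipeline at a CSV (column names are
remappable via a `ColumnDialect`):

```bash
ponvbart run config.yaml --out run_dir
```

with `config.yaml` like

```yaml
input: {kind: csv, path: cohort.csv}
model: {m: 50, ndpost: 1000, nskip: 100}
seed: 20
```

The `examples/` directory contains one short narrative script per
capability (descriptives, simulation, BART fitting, g-computation,
propensity validation, full pipeline).

## Documentation

`docs/methods.md` describes the model, priors, MCMC scheme, causal
estimand, generator design, and numerical choices in full.
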