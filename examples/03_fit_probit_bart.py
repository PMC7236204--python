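"""Fit the probit BART outcome model and inspect its predictions.

The sampler implements Albert-Chib latent augmentation with Bayesian
backfitting over a sum of regression trees; posterior draws are stored
so any counterfactual design matrix can be pushed through later.
"""

from ponvbart.bart import BartConfig, fit_pbart
from ponvbart.cohort import build_feature_matrix
from ponvbart.simulate import SimConfig, simulate_cohort

records, _ = simulate_cohort(SimConfig(n=2000, seed=21))
features = build_feature_matrix(records)

config = BartConfig(m=50, ndpost=500, nskip=100, seed=0)
fit = fit_pbart(features.X, features.y, config)

probs = fit.predict_mean(features.X)
print(f"posterior mean P(PONV) over cohort: {probs.mean():.3f} "
      f"(observed incidence {features.y.mean():.3f})")
print(f"per-subject range: {probs.min():.3f} - {probs.max():.3f}")

fit.save("bart_fit.json")
print("saved posterior to bart_fit.json (reload with BartPosterior.load)")
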