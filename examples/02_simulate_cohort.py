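"""Generate a synthetic confounded cohort with known ground truth.

The generator draws covariates from realistic marginals, assigns
cannabis-use level through a confounded multinomial-logit model (daily
users are more often male, smokers, with prior PONV and PACU opioids),
and draws the outcome from a probit model.  Because assignment depends
on outcome-relevant covariates, the crude RR is biased; the brute-force
oracle gives the true causal sATE to compare against.
"""

import numpy as np

from ponvbart.simulate import SimConfig, simulate_cohort, write_fixture

records, truth = simulate_cohort(SimConfig(n=5000, seed=11))

levels = np.array([r.cannabis_use for r in records])
y = np.array([r.ponv_observed for r in records])
print(f"n = {len(records)}; daily {100 * (levels == 'daily').mean():.1f}%, "
      f"current {100 * (levels == 'current').mean():.1f}%")
crude_rr = y[levels == "daily"].mean() / y[levels == "none"].mean()
print(f"crude daily-vs-none RR (confounded): {crude_rr:.3f}")
print(f"true causal sATE RR (oracle):        "
      f"{truth.pooled['daily_vs_none']['rr']:.3f}")

write_fixture(records, "cohort.csv")
print("wrote cohort.csv (round-trips byte-identically through load_cohort)")
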