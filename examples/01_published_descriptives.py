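"""Reproduce the published cohort descriptives from packaged aggregates.

The package ships the per-stratum aggregate counts of the source study
(stratum sizes, observed PONV counts) as a small JSON fixture.  This
example recomputes the headline descriptive statistics from them.
"""

from ponvbart.cohort import load_table1_fixture, summarize_aggregate

agg = summarize_aggregate(load_table1_fixture())

print(f"analyzed cohort: n = {agg['total_n']}")
for level in ("none", "current", "daily"):
    row = agg["levels"][level]
    print(f"  {level:8s} n = {row['n']:6d} ({row['pct_of_total']:.1f}%), "
          f"observed PONV {row['ponv_observed']['pct']:.1f}%")
print(f"any cannabis use: {agg['any_cannabis']['pct']:.1f}%")
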