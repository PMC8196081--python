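"""Flag close relatives from a PI_HAT table and prune them greedily.

Pairs are flagged when PI_HAT exceeds 0.15 and a per-population outlier
threshold built from the mean/median and SD/MAD of within-population values;
flagged individuals are removed most-paired-first until no pair survives.
"""

import pandas as pd

from copydist import preprocess, simulate

cohort = simulate.simulate_cohort(
    simulate.default_scenario(seed=3, n_groups=12, n_per_group=8, relative_rate=0.15)
)
pops = cohort.metadata["group"]

report = preprocess.prune_report(cohort.pihat, pops)
planted = cohort.pihat[cohort.pihat["planted"]]
removed = set(report["removed"])
caught = sum(bool({a, b} & removed) for a, b in zip(planted.iid1, planted.iid2))

print(f"flagged pairs:            {report['n_flagged_pairs']}")
print(f"individuals removed:      {report['n_removed']}")
print(f"planted relative pairs:   {len(planted)}, broken by pruning: {caught}")
print(f"surviving pairs >= 0.2:   {report['n_surviving_pairs_ge_0.2']}")

# Within-group diversity: homozygous genotype counts vs census size.
rng = __import__("numpy").random.default_rng(0)
census = pd.Series(rng.uniform(1e4, 1e6, size=12), index=sorted(pops.unique()))
diversity = pd.Series(2e5 - 0.05 * census + rng.normal(0, 2e3, size=12), index=census.index)
slope, p = preprocess.diversity_vs_census(diversity, census)
print(f"homozygosity vs census:   slope {slope:.3f}, p {p:.2e} "
      "(negative: larger groups are more diverse)")
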