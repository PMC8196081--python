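"""Generate a synthetic cohort and write every table to disk.

The cohort emulates a haplotype-painted survey of ethnic groups scattered
over an Ethiopia-sized region: copying profiles whose similarity decays
exponentially with distance, per-individual birthplaces and elevations,
language/religion metadata, a cultural-trait table, a PI_HAT relatedness
table with planted relatives, and shared MRCA segment summaries.
"""

from copydist import simulate

config = simulate.default_scenario(seed=1)
cohort = simulate.simulate_cohort(config)
cohort.write("scratch_cohort")

print(f"groups:              {config.n_groups}")
print(f"individuals:         {len(cohort.metadata)}")
print(f"donor features:      {cohort.internal.shape[1]} (internal panel)")
print(f"planted decay:       similarity ~ {config.alpha_shared} + "
      f"{config.beta_geo}*exp(-{config.lambda_geo}*d_km)")
print(f"planted relatives:   {int(cohort.pihat['planted'].sum())} pairs above PI_HAT 0.25")
print("tables written to scratch_cohort/ (metadata, profiles, traits, PI_HAT, segments)")
# The decay parameters are the ground truth the spatial module should recover.
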