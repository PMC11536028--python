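"""Derive positivity cutoffs and stage a cohort.

Tau cutoffs come from the amyloid-negative CU reference stratum
(mean + 2.5 SD per composite ROI); amyloid positivity is Centiloid >= 25;
the moderate/high temporoparietal boundary is the fixed 2.68 SUVR.  The
stage table shows how plasma pTau217 climbs with advancing biological
stage, and the Braak table the same along the topographic staging axis.
"""

from ptaupet import build_threshold_set, default_config, generate_cohort, stage_table

cohort = generate_cohort(default_config(seed=1))
thresholds = build_threshold_set(cohort)

print("tau positivity cutoffs (SUVR):")
for name in ("Me", "Te", "R", "MetaT"):
    print(f"  {name:6s} {thresholds.tau_cutoffs[name]:.3f}")
print(f"  Te moderate/high boundary: {thresholds.te_high_cutoff:.2f} SUVR")

print("\nbiological stages (counts and pTau217 medians, pg/ml):")
print(stage_table(cohort, thresholds, by="biological").to_string(index=False))

print("\nPET Braak stages:")
print(
    stage_table(cohort, thresholds, by="braak", merge_braak_ii=True)
    .to_string(index=False)
)
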