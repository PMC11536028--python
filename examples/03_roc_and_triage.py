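"""ROC analysis and two-threshold triage for amyloid-PET status.

Evaluates how well plasma pTau217 predicts amyloid positivity: first with
a single Youden-index cutoff (one threshold, binary call), then with a
two-threshold strategy (a 95%-sensitivity lower threshold and a
90%-specificity upper threshold) that leaves an indeterminate zone where
no call is made.  The triage trade: a few untriaged participants buy a
higher correct-classification rate among those called.
"""

import numpy as np

from ptaupet import (
    default_config,
    generate_cohort,
    roc_curve,
    threshold_at_sensitivity,
    threshold_at_specificity,
    two_threshold_classify,
    youden_point,
)

cohort = generate_cohort(default_config(seed=1))
scores = np.array([r.ptau217 for r in cohort])
abeta = np.array([r.centiloid >= 25 for r in cohort]).astype(int)

roc = roc_curve(scores, abeta)
point = youden_point(roc)
print(f"amyloid status: AUC = {roc.auc:.3f}  (n = {len(cohort)})")
print(
    f"Youden threshold {point.threshold:.3f} pg/ml: "
    f"sens {point.sens:.2f}, spec {point.spec:.2f}, "
    f"PPV {point.ppv:.2f}, NPV {point.npv:.2f}, accuracy {point.accuracy:.2f}"
)

lower = threshold_at_sensitivity(roc, 0.95).threshold
upper = threshold_at_specificity(roc, 0.90).threshold
zones = two_threshold_classify(scores, abeta, lower, upper)
print(
    f"\ntriage thresholds: lower {lower:.3f} (95% sens), "
    f"upper {upper:.3f} (90% spec)"
)
print(
    f"zones: low {100 * zones.frac_low:.1f}%  "
    f"indeterminate {100 * zones.frac_ind:.1f}%  "
    f"high {100 * zones.frac_high:.1f}%"
)
print(
    f"correct: low zone {100 * zones.pct_low_correct:.0f}%  "
    f"high zone {100 * zones.pct_high_correct:.0f}%  "
    f"overall (excl. indeterminate) {100 * zones.overall_correct:.0f}%"
)
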