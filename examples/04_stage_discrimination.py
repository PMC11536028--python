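"""Discriminating advanced biological stages with logistic models.

Fits three logistic models for the moderate/high-tau contrast (Intermediate
or Advanced stage vs everyone below): plasma pTau217 alone, a base model of
age + sex + APOE e4, and the full combination.  DeLong's test compares the
correlated AUCs; a tiny p-value against the base model means the blood
biomarker carries most of the staging signal, and a null comparison against
the full model means covariates add nothing on top of it.
"""

import numpy as np

from ptaupet import (
    build_threshold_set,
    default_config,
    delong_compare,
    fit_logistic,
    generate_cohort,
    roc_curve,
    stage_cohort,
)

cohort = generate_cohort(default_config(seed=1))
staged = stage_cohort(cohort, build_threshold_set(cohort))

keep = staged["biological_stage"] != "Atypical"
y = staged.loc[keep, "biological_stage"].isin(["Intermediate", "Advanced"])
y = y.to_numpy().astype(int)
ptau = staged.loc[keep, "ptau217"].to_numpy()
age = np.array([r.age for r, k in zip(cohort, keep) if k])
male = np.array([1.0 if r.sex == "male" else 0.0 for r, k in zip(cohort, keep) if k])
apoe = np.array([1.0 if r.apoe4 else 0.0 for r, k in zip(cohort, keep) if k])

designs = {
    "pTau217 only": ptau[:, None],
    "base (age+sex+APOE)": np.column_stack([age, male, apoe]),
    "full": np.column_stack([ptau, age, male, apoe]),
}
predicted = {}
for name, X in designs.items():
    fit = fit_logistic(X, y)
    predicted[name] = fit.predicted
    print(f"{name:22s} AUC = {roc_curve(fit.predicted, y).auc:.3f}")

for other in ("base (age+sex+APOE)", "full"):
    cmp = delong_compare(predicted["pTau217 only"], predicted[other], y)
    print(
        f"DeLong pTau217 vs {other}: dAUC = {cmp.auc_diff:+.3f}, "
        f"z = {cmp.z:+.2f}, p = {cmp.p:.2e}"
    )
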