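# Methods

## Scope and model

The package evaluates a plasma phospho-tau concentration (pTau217, pg/ml)
as a predictor of PET-defined amyloid status, tau status, and disease
stage.  Its components are (1) a synthetic cohort generator with truth
labels, (2) composite tau-ROI quantification, (3) positivity-threshold
derivation, (4) Braak and biological staging, (5) a diagnostic-accuracy
suite, and (6) a pipeline that sequences them into a deterministic report
bundle.

## Composite ROIs

Composites are unweighted means of member-region SUVR.  Whether such
composites should be volume-weighted is not settled; equal weighting is
the documented default, and per-region weights can be supplied for
volume weighting.  Region names are normalised (lower-case,
spaces/hyphens → underscores) before lookup; near-synonymous names for
the same anatomical structure (parahippocampus/parahippocampal) are
canonicalised to a single token.  The temporoparietal list names the
angular gyrus separately even though the Desikan-Killiany parcellation
folds it into inferior parietal; it is carried as its own region so the
composite definitions match their published form.

## Thresholds

* Amyloid: Centiloid ≥ 25 (inclusive); a 10–50 CL sensitivity sweep is
  supported.  Tau positivity is strictly greater-than its cutoff — the
  amyloid inequality is stated in the source criteria, the tau convention
  is this package's documented choice.
* Tau: per-composite mean + k·SD (k = 2.5, sample SD with n−1) over the
  amyloid-negative CU reference stratum, or an upper percentile (default
  95th, linear interpolation between order statistics, the "type 7" rule;
  the convention is configurable because none is canonical).
* Moderate/high Te boundary: fixed at 2.68 SUVR by default (the
  literature-derived upper quartile of Aβ+ MCI/dementia tau PET from a
  larger imaging sample than a desk-scale cohort can reproduce); a
  `derive` mode recomputes the upper quartile from the supplied cohort.
* PART handling: an optional, off-by-default rule drops amyloid-negative
  reference participants whose Me composite exceeds a provisional Me
  cutoff from the Braak-composite reference stratum before recomputing
  those cutoffs once.  Published criteria for primary age-related
  tauopathy exclusion are not specified precisely; this operationalisation
  is the package's own stand-in and is labelled as such.

## Staging rules

Braak stage = length of the positivity prefix over the six Braak
composites; any positive composite preceded by a negative one is
Atypical.  Grouped stages (I–II / III–IV / V–VI) and the low (0–III) vs
high (IV–VI) dichotomy are pure functions of stage.  Sparse Braak II can
be merged into an I–II reporting row; staging itself keeps II distinct.

Biological stage is evaluated in the order: amyloid-negative and
tau-negative → A−T−; amyloid-negative with any tau positivity → Atypical;
A+ all-negative → Initial; A+ with Te SUVR above the moderate/high
boundary → Advanced; A+ Te-positive otherwise → Intermediate (regardless
of Me/R status — Te drives the moderate/high split); A+ with Me-positive,
Te- and R-negative → Early; anything else (e.g. A+ R-positive without Te)
→ Atypical.  How an R-positive/Te-negative profile should be staged is
genuinely open; Atypical is the package's documented choice.

## Diagnostic-accuracy machinery

* ROC: candidate thresholds are the unique observed scores plus a
  sentinel above the maximum; the rule is score ≥ threshold ⇒ positive,
  so operating points land on observed concentrations.  AUC is the
  Mann–Whitney rank statistic with ties counted ½, identical to the
  trapezoidal area along the threshold-swept trace (asserted on
  randomized instances).
* Youden point: exhaustive maximum of sens + spec − 1; ties break toward
  the lowest threshold, i.e. the most sensitive maximiser, fitting a
  screening context.
* Fixed-target points: at target sensitivity, the largest threshold still
  meeting it (maximising specificity); at target specificity, the
  smallest threshold meeting it.  A specificity target attainable only at
  the degenerate all-negative sentinel raises an error reporting the
  maximum attainable value.
* PPV/NPV are raw, never prevalence-adjusted; undefined ratios (empty
  denominator) are reported missing, not zero.
* Bootstrap: percentile method, B = 1000, level 0.95, paired row
  resampling, seeded.  The conventional with-replacement bootstrap is the
  default; an m-out-of-n subsampling mode (m = n//2 without replacement,
  approximate and documented as such) is selectable.  Replicates on which
  the statistic fails (e.g. a single-class resample) are redrawn up to a
  cap; the call errors if more than 10% fail.  Youden-threshold intervals
  are produced by re-deriving the ROC and its operating point inside each
  replicate, so they reflect threshold re-estimation.
* DeLong: structural components (placement values) computed via midranks;
  variance of the AUC difference from the placement covariances; standard
  normal reference, two-sided.  Zero-variance zero-difference returns
  p = 1 by convention.
* Group comparisons: Shapiro–Wilk on pooled within-group residuals at
  α = 0.05 gates one-way ANOVA vs Kruskal–Wallis; pairwise contrasts use
  Tukey's HSD (FWER 0.05).  Categorical contrasts use the chi-square test
  without continuity correction.  Families of correlation/DeLong p-values
  are Bonferroni-adjusted (min(1, m·p)).
* Logistic combination models: maximum likelihood (Newton/IRLS, tolerance
  1e−8, ≤100 iterations) with an intercept always included, via
  statsmodels; complete separation is caught and flagged, singular
  designs raise.  Stage-model AUC confidence intervals resample fixed
  predicted probabilities rather than refitting the model per replicate —
  the common practice in diagnostic-accuracy reporting and a deliberate
  runtime choice.

## Synthetic cohort generator

The generator is hierarchical, mirroring the staging logic so that truth
labels exist for recovery tests:

    group → amyloid status → biological stage → (true Braak stage,
        Centiloid, regional SUVRs, pTau217, covariates)

Defaults encode the study conditions: group sizes 156/100/132
(CU/MCI/dementia); amyloid prevalence 0.40/0.69/0.89; biological-stage
mixes among A+ participants taken from the published stage counts (whole
cohort 96/15/79/57 across Initial/Early/Intermediate/Advanced, with the
cognitively-impaired mix applied to both MCI and dementia because no
finer breakdown is printed); stage-wise pTau217 medians 0.1/0.2/0.4/0.6/
0.9 pg/ml with log-normal dispersion σ = 0.35 (concentrations are
positive and right-skewed; the printed interquartile ranges are
asymmetric, and σ = 0.35 reproduces their width at one-decimal printed
precision).  Centiloid is truncated-normal near zero for A− strata
(medians −0.9 to 2.5, scale 8, truncated to [−10, 25)) and a 25-shifted
log-normal matched to the printed A+ medians (79.3/113.0/113.4).  The
distributional families are modelling choices, not claims about the
source data, which publishes only medians and IQRs.

Tau profiles: each region belongs to the earliest Braak composite that
contains it; regions outside the Braak lists are mapped by anatomical
analogy (angular and the prefrontal/orbitofrontal/rectus members of R to
stage V, anterior cingulate to IV).  A participant with true Braak stage
k elevates all regions of stage ≤ k by a participant-level magnitude
drawn per biological stage (Early 0.3–0.5, Intermediate 0.45–1.65,
Advanced 2.0–3.4 SUVR), damped ×0.6 in mesial regions and fusiform
(matching the lower mesial signal of the tracer at matched stage), on a
baseline of 1.0 ± 0.05 SUVR.  True Braak stage conditional on biological
stage: Early II/III (0.25/0.75), Intermediate IV/V (0.5/0.5), Advanced
V/VI (0.4/0.6); tau-negative stages are Braak 0.

Internal consistency is guaranteed by rejection sampling: a record's
composite values must reproduce its intended Braak prefix and biological
stage when thresholded at the design cutoffs (baseline mean + 2.5
composite SD), with a safety margin of 1–1.5 composite SDs on either
side.  This is what makes cohort-wide assertions ("with atypical_rate = 0
every profile is prefix-consistent under cohort-derived thresholds")
hold deterministically; pure additive noise could not guarantee them.
Atypical profiles flip one randomly chosen earlier Braak composite of a
stage ≥ III record to baseline while leaving later composites positive
(the simplest construction violating prefix order); flips that would
contradict the record's biological stage are re-chosen, and stage-II
records are ineligible because no flip keeps their mesial positivity
geometrically consistent.  The default atypical rate is 0.09 among
eligible records, yielding a few percent of the cohort, the order
observed in PET staging practice.

Reproducibility: every participant draws from an RNG sub-stream keyed by
(seed, participant index), so output is bit-identical across runs and
independent of generation order.

What the generator does *not* emulate: longitudinal change, assay
measurement error beyond log-normal dispersion, covariate–biomarker
correlations within stage (age, sex and APOE affect stage membership only
through the printed per-stratum proportions), PET image noise, and
partial-volume effects.  Passing tests therefore demonstrate that the
analysis machinery is correct and calibrated under the stated generative
assumptions — not that real cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

Ties at a positivity cutoff are negative (strict inequality).  Reported
percentages round half away from zero to integers.  Empty analysis strata
(e.g. a CU-only cohort's impaired subgroup) are skipped with a logged
warning, never a crash; records missing optional covariates are dropped
from combination models only, with a logged count.  The two-threshold
classifier treats boundary scores as indeterminate.  When the
high-sensitivity lower threshold exceeds the high-specificity upper
threshold (discrimination strong enough that the targets cross), no
indeterminate zone is feasible; the pipeline collapses both thresholds to
the single Youden cutoff and flags the row as collapsed.  Percentile and
quartile computations use linear interpolation throughout.

## Problem sizes

Default analyses run on the 388-record synthetic cohort with B = 1000
bootstrap replicates.  Calibration suites use 2000 null simulations for
the DeLong type-I check, 500 replications at n = 300 for bootstrap
coverage, and 20000 simulations for the power cross-check — sizes chosen
so Monte-Carlo error is small relative to the tolerances asserted.

## Known limitations

The fold-change profile across clinical groups is slightly compressed
relative to its anchors (MCI and dementia share a stage mix, so their A+
medians nearly coincide); meta-temporal SUVR in Advanced records runs
somewhat above the printed upper quartiles; grouped Braak I–II medians
rest on very few records.  The headline cohort quantities (AUCs ≈
0.93–0.96, Spearman r ≈ 0.7–0.8, triage fractions) are properties of the
generative conditions and will not numerically match any particular real
cohort.
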