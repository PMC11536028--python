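"""Diagnostic-accuracy statistics for a continuous biomarker.

ROC analysis uses the observed unique scores (plus a sentinel above the
maximum) as candidate thresholds with the rule ``score >= threshold =>
predicted positive``, so operating points fall on observed concentrations.
AUC is the Mann-Whitney rank statistic with ties counted 1/2, which equals
the trapezoidal area under the empirical ROC trace.

Operating points: Youden's index (ties broken toward the lowest threshold,
i.e. the most sensitive maximiser), or thresholds fixed at a target
sensitivity / specificity.  Predictive values are raw, never adjusted for
prevalence (a prevalence-adjusted variant is available but off by default).

Confidence intervals use the percentile bootstrap (default 1000 replicates,
with replacement; an m-out-of-n without-replacement subsampling mode is
selectable).  Correlated AUCs are compared with DeLong's test via
structural components (placement values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.power import TTestIndPower
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ROCResult",
    "OperatingPoint",
    "ConfusionMetrics",
    "ZoneClassification",
    "CorrelationResult",
    "ModelComparison",
    "LogisticFit",
    "GroupComparison",
    "roc_curve",
    "auc_trapezoid",
    "youden_point",
    "threshold_at_sensitivity",
    "threshold_at_specificity",
    "operating_point_at",
    "operating_metrics",
    "bootstrap_ci",
    "spearman",
    "delong_compare",
    "fit_logistic",
    "two_threshold_classify",
    "compare_groups",
    "chi_square",
    "cohens_d",
    "power_two_sample",
    "bonferroni",
]


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.astype(int)
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1 or bool)")
    return arr.astype(int)


@dataclass
class ROCResult:
    """Full ROC trace with AUC; retains scores/labels for resampling."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    auc_ci: tuple[float, float] | None = None
    orientation: str = "higher score => positive"
    scores: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """Empirical ROC over the observed unique scores plus a sentinel.

    Requires at least one record of each class and finite scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels contain a single class; ROC is undefined")
    uniq = np.unique(scores)
    thresholds = np.append(uniq, uniq[-1] + 1.0)  # sentinel: nothing positive
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    # sens(t) = P(pos >= t), spec(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / n_neg
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=_rank_auc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
        scores=scores,
        labels=labels,
    )


def auc_trapezoid(roc: ROCResult) -> float:
    """Trapezoidal area under the ROC trace (independent of the rank formula)."""
    # integrate along the threshold-swept path; thresholds ascend, so fpr
    # descends and reversing gives an ascending integration variable
    fpr = 1.0 - roc.spec
    return float(np.trapezoid(roc.sens[::-1], fpr[::-1]))


@dataclass
class ConfusionMetrics:
    """Confusion-matrix summary; undefined ratios are None, never 0."""

    sens: float | None
    spec: float | None
    ppv: float | None
    npv: float | None
    accuracy: float


@dataclass
class OperatingPoint:
    """A single threshold with its confusion metrics and Youden's J."""

    threshold: float
    sens: float
    spec: float
    ppv: float | None
    npv: float | None
    accuracy: float
    youden_j: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def operating_metrics(predicted: Sequence, truth: Sequence) -> ConfusionMetrics:
    """sens/spec/PPV/NPV/accuracy from binary predictions and truth."""
    predicted = _as_binary(predicted)
    truth = _as_binary(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("truth contains a single class")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return ConfusionMetrics(
        sens=ratio(tp, tp + fn),
        spec=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=(tp + tn) / truth.size,
    )


def operating_point_at(roc: ROCResult, threshold: float) -> OperatingPoint:
    """Evaluate all operating metrics at a given threshold."""
    predicted = (roc.scores >= threshold).astype(int)
    m = operating_metrics(predicted, roc.labels)
    return OperatingPoint(
        threshold=float(threshold),
        sens=m.sens,
        spec=m.spec,
        ppv=m.ppv,
        npv=m.npv,
        accuracy=m.accuracy,
        youden_j=m.sens + m.spec - 1.0,
    )


def youden_point(roc: ROCResult) -> OperatingPoint:
    """Threshold maximising sens + spec - 1; ties go to the lowest threshold."""
    j = roc.sens + roc.spec - 1.0
    idx = int(np.argmax(j))  # thresholds ascending; first max = most sensitive
    return operating_point_at(roc, roc.thresholds[idx])


def threshold_at_sensitivity(roc: ROCResult, target: float) -> OperatingPoint:
    """Largest threshold keeping sensitivity >= target (max specificity)."""
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target sensitivity must be in (0, 1], got {target}")
    qualifying = np.flatnonzero(roc.sens >= target - 1e-12)
    idx = int(qualifying[-1])  # sens is non-increasing: qualifying is a prefix
    return operating_point_at(roc, roc.thresholds[idx])


def threshold_at_specificity(roc: ROCResult, target: float) -> OperatingPoint:
    """Smallest threshold reaching specificity >= target (max sensitivity).

    Raises when the target is only attainable at the degenerate
    all-negative sentinel (e.g. heavily tied scores), reporting the maximum
    attainable specificity at a non-degenerate threshold.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target specificity must be in (0, 1], got {target}")
    qualifying = np.flatnonzero(roc.spec >= target - 1e-12)
    idx = int(qualifying[0])  # spec is non-decreasing: qualifying is a suffix
    point = operating_point_at(roc, roc.thresholds[idx])
    if idx == roc.thresholds.size - 1 and point.sens == 0.0:
        max_attainable = float(roc.spec[-2]) if roc.spec.size > 1 else 0.0
        raise ValueError(
            f"specificity target {target} only attainable with zero "
            f"sensitivity; maximum attainable is {max_attainable:.3f}"
        )
    return point


# --- bootstrap -----------------------------------------------------------


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence | tuple[Sequence, ...],
    *,
    B: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    scheme: str = "resample",
    retry_cap: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``statistic(data)``.

    ``data`` may be one array or a tuple of aligned arrays (rows are
    resampled jointly, i.e. paired resampling).  ``scheme="resample"`` is
    the conventional with-replacement bootstrap; ``scheme="subsample"``
    draws m = n//2 rows without replacement (an approximate m-out-of-n
    alternative).  Replicates on which the statistic raises are redrawn up
    to ``retry_cap`` times; the call errors if more than 10% of replicates
    fail outright.
    """
    if B < 100:
        raise ValueError(f"need at least 100 bootstrap replicates, got {B}")
    if scheme not in ("resample", "subsample"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    if n < 2:
        raise ValueError(f"need at least 2 rows to bootstrap, got {n}")
    rng = np.random.default_rng(rng)
    m = n if scheme == "resample" else max(2, n // 2)
    replace = scheme == "resample"

    values = np.empty(B)
    failures = 0
    for b in range(B):
        for _ in range(retry_cap):
            idx = rng.choice(n, size=m, replace=replace)
            try:
                values[b] = statistic(*(a[idx] for a in arrays))
                break
            except Exception:
                continue
        else:
            values[b] = np.nan
            failures += 1
    if failures > 0.1 * B:
        raise RuntimeError(
            f"statistic failed on {failures}/{B} bootstrap replicates"
        )
    values = values[np.isfinite(values)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# --- correlation ----------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    ci: tuple[float, float] | None
    n: int


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    ci: bool = True,
    B: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties) with bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    r = float(stats.spearmanr(x, y).statistic)
    interval = None
    if ci:
        interval = bootstrap_ci(
            lambda a, b: stats.spearmanr(a, b).statistic,
            (x, y),
            B=B,
            level=level,
            rng=rng,
        )
    return CorrelationResult(r=r, ci=interval, n=int(x.size))


# --- DeLong ---------------------------------------------------------------


@dataclass
class ModelComparison:
    auc_a: float
    auc_b: float
    auc_diff: float
    variance: float
    z: float
    p: float


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> ModelComparison:
    """DeLong's test for two correlated (paired) AUCs.

    Variance of the AUC difference comes from the empirical covariance of
    the placement values; the reference distribution is standard normal
    (two-sided).  A degenerate zero-variance, zero-difference comparison
    returns p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = _as_binary(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")
    v10_a, v01_a, auc_a = _placements(a, labels)
    v10_b, v01_b, auc_b = _placements(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    variance = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if variance <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(variance)
        p = float(2 * stats.norm.sf(abs(z)))
    return ModelComparison(
        auc_a=auc_a, auc_b=auc_b, auc_diff=diff, variance=float(variance),
        z=float(z), p=p,
    )


# --- logistic combination models -----------------------------------------


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first in ``coefficients``)."""

    coefficients: np.ndarray
    predicted: np.ndarray
    converged: bool
    separation: bool


def fit_logistic(features: Sequence, labels: Sequence) -> LogisticFit:
    """Fit a logistic regression and return predicted probabilities.

    The intercept is always included.  Complete separation is detected and
    flagged (coefficients diverge); a singular design raises.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular design matrix")
    if y.size <= Xc.shape[1]:
        raise ValueError("need more observations than coefficients")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, Xc).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
            converged = bool(result.mle_retvals["converged"])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            result = sm.Logit(y, Xc).fit(method="bfgs", maxiter=200, disp=0)
            converged = False
    coefficients = np.asarray(result.params, dtype=float)
    if np.abs(coefficients).max() > 50:
        separation = True
    return LogisticFit(
        coefficients=coefficients,
        predicted=np.asarray(result.predict(Xc), dtype=float),
        converged=converged,
        separation=separation,
    )


# --- two-threshold triage -------------------------------------------------


@dataclass
class ZoneClassification:
    """Low / Indeterminate / High triage of a continuous score.

    Scores strictly below ``lower`` are Low, strictly above ``upper`` are
    High, boundary values are Indeterminate.  Correct-classification
    percentages treat High as a positive call and Low as a negative call;
    ``overall_correct`` excludes the Indeterminate zone.  Zone-conditional
    metrics are None when the zone is empty.
    """

    lower: float
    upper: float
    zones: np.ndarray
    frac_low: float
    frac_ind: float
    frac_high: float
    pct_high_correct: float | None
    pct_low_correct: float | None
    overall_correct: float | None


def two_threshold_classify(
    scores: Sequence[float], labels: Sequence, lower: float, upper: float
) -> ZoneClassification:
    if lower > upper:
        raise ValueError(f"lower ({lower}) must be <= upper ({upper})")
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels)
    zones = np.where(
        scores < lower, "Low", np.where(scores > upper, "High", "Indeterminate")
    )
    n = scores.size
    low = zones == "Low"
    high = zones == "High"
    n_low, n_high = int(low.sum()), int(high.sum())
    pct_low = float((labels[low] == 0).mean()) if n_low else None
    pct_high = float((labels[high] == 1).mean()) if n_high else None
    agree = int((labels[low] == 0).sum() + (labels[high] == 1).sum())
    overall = agree / (n_low + n_high) if (n_low + n_high) else None
    return ZoneClassification(
        lower=float(lower),
        upper=float(upper),
        zones=zones,
        frac_low=n_low / n,
        frac_ind=float((zones == "Indeterminate").mean()),
        frac_high=n_high / n,
        pct_high_correct=pct_high,
        pct_low_correct=pct_low,
        overall_correct=overall,
    )


# --- group comparisons ----------------------------------------------------


@dataclass
class GroupComparison:
    test: str  # "anova" or "kruskal"
    statistic: float
    p: float
    shapiro_p: float
    pairwise: pd.DataFrame


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Omnibus comparison with Tukey-HSD pairwise contrasts.

    Shapiro-Wilk on the pooled within-group residuals (alpha = 0.05)
    selects one-way ANOVA (normal) vs Kruskal-Wallis (non-normal); pairwise
    contrasts use Tukey's HSD at family-wise error rate 0.05.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 3:
            raise ValueError(f"group {name!r} has {arr.size} values; need >= 3")
    residuals = np.concatenate([a - a.mean() for a in arrays.values()])
    if np.ptp(residuals) == 0:
        shapiro_p = 1.0  # identical values: trivially no evidence against normality
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    values = list(arrays.values())
    if np.ptp(np.concatenate(values)) == 0:
        test, statistic, p = ("anova", 0.0, 1.0)
    elif shapiro_p >= 0.05:
        res = stats.f_oneway(*values)
        test, statistic, p = "anova", float(res.statistic), float(res.pvalue)
    else:
        res = stats.kruskal(*values)
        test, statistic, p = "kruskal", float(res.statistic), float(res.pvalue)
    stacked = np.concatenate(values)
    labels = np.concatenate([[name] * arr.size for name, arr in arrays.items()])
    if np.ptp(stacked) == 0:
        pairs = [
            {"group1": a, "group2": b, "p_adj": 1.0, "reject": False}
            for i, a in enumerate(arrays)
            for b in list(arrays)[i + 1:]
        ]
        pairwise = pd.DataFrame(pairs)
    else:
        tukey = pairwise_tukeyhsd(stacked, labels, alpha=0.05)
        uniq = np.unique(labels)
        combos = list(combinations(uniq, 2))
        pairwise = pd.DataFrame(
            {
                "group1": [a for a, _ in combos],
                "group2": [b for _, b in combos],
                "p_adj": np.asarray(tukey.pvalues, dtype=float),
                "reject": np.asarray(tukey.reject, dtype=bool),
            }
        )
    return GroupComparison(
        test=test, statistic=statistic, p=p, shapiro_p=shapiro_p, pairwise=pairwise
    )


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float, int]:
    """Chi-square test of independence without continuity correction."""
    res = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardised mean difference with pooled (n-1 weighted) SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def power_two_sample(
    n_per_group: int, effect_size: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-sample t-test (noncentral t)."""
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    if effect_size < 0:
        raise ValueError(f"effect_size must be >= 0, got {effect_size}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(
        TTestIndPower().power(
            effect_size=effect_size,
            nobs1=n_per_group,
            alpha=alpha,
            ratio=1.0,
            alternative="two-sided",
        )
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p); m defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)
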