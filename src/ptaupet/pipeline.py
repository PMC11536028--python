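"""End-to-end analysis pipeline.

Orchestrates the full evaluation over a cohort: threshold derivation,
Braak and biological staging, pTau217-vs-PET correlations, ROC suites for
amyloid status (across a Centiloid cutoff sweep), tau status per composite
ROI (under both tau threshold methods) and the Braak low/high dichotomy,
two-threshold triage into Low / Indeterminate / High zones, and logistic
stage-discrimination models (pTau217-only vs an age+sex+APOEe4 base model
vs the full model) compared with DeLong's test.

Reruns with the same inputs and seed produce byte-identical report bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ParticipantRecord, read_cohort_csv
from .thresholds import ThresholdSet, abeta_positive, build_threshold_set, composite_values
from .staging import stage_cohort, stage_table
from . import evaluate as ev

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_analysis",
    "prevalence_summary",
    "fold_change_summary",
    "group_abeta_table",
]

log = logging.getLogger(__name__)

_STAGED = ("Initial", "Early", "Intermediate", "Advanced")
_CONTRASTS = {
    "A+ vs A-T-": _STAGED,
    "MOD/HIGH vs rest": ("Intermediate", "Advanced"),
    "HIGH vs rest": ("Advanced",),
}


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis run."""

    cl_cutoff: float = 25.0
    cl_sweep: tuple[float, ...] | None = None
    tau_method: str = "mean_plus_k_sd"
    k: float = 2.5
    p: float = 95.0
    te_high_mode: str | float = "fixed"  # "fixed" | "derive" | explicit SUVR
    bootstrap_b: int = 1000
    level: float = 0.95
    seed: int = 0
    zone_targets: tuple[tuple[float, float], ...] = ((0.90, 0.90), (0.95, 0.90))
    subgroups: tuple[str, ...] = ("all", "CU", "CI")

    def __post_init__(self) -> None:
        if self.cl_sweep is not None:
            self.cl_sweep = tuple(float(c) for c in self.cl_sweep)
            if any(not 10.0 <= c <= 50.0 for c in self.cl_sweep):
                raise ValueError(
                    f"cl_sweep values must lie in [10, 50], got {self.cl_sweep}"
                )
        for sens_t, spec_t in self.zone_targets:
            if not (0.0 < sens_t <= 1.0 and 0.0 < spec_t <= 1.0):
                raise ValueError(
                    f"zone targets must be in (0, 1], got ({sens_t}, {spec_t})"
                )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    thresholds: ThresholdSet
    staging: pd.DataFrame
    correlations: pd.DataFrame
    roc_summary: pd.DataFrame
    zones: pd.DataFrame
    stage_models: pd.DataFrame
    stage_medians: pd.DataFrame
    braak_medians: pd.DataFrame
    prevalence: pd.DataFrame
    fold_changes: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.thresholds.to_json(str(out / "thresholds.json"))
        for name in (
            "staging",
            "correlations",
            "roc_summary",
            "zones",
            "stage_models",
            "stage_medians",
            "braak_medians",
            "prevalence",
            "fold_changes",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def prevalence_summary(
    cohort: Sequence[ParticipantRecord], cl_cutoff: float = 25.0
) -> pd.DataFrame:
    """Per-group and overall amyloid-PET positivity percentages.

    Percentages are integer-rounded, halves away from zero.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    groups = {"CU": [], "MCI": [], "dementia": []}
    for r in cohort:
        groups[r.group].append(abeta_positive(r.centiloid, cl_cutoff))
    for name, flags in [*groups.items(), ("overall", [f for v in groups.values() for f in v])]:
        if not flags:
            continue
        n_pos = sum(flags)
        rows.append(
            {
                "group": name,
                "n": len(flags),
                "n_abeta_pos": n_pos,
                "prevalence_pct": _round_half_away(100.0 * n_pos / len(flags)),
            }
        )
    return pd.DataFrame(rows)


def fold_change_summary(
    table: pd.DataFrame,
    reference: str,
    stage_col: str = "stage",
    median_col: str = "ptau217_median",
) -> pd.DataFrame:
    """Ratios of stratum medians to a reference stratum median (1 decimal)."""
    ref_rows = table.loc[table[stage_col] == reference, median_col]
    if ref_rows.empty or not np.isfinite(ref_rows.iloc[0]) or ref_rows.iloc[0] <= 0:
        raise ValueError(
            f"reference stratum {reference!r} is empty or has non-positive median"
        )
    ref = float(ref_rows.iloc[0])
    out = table[[stage_col, median_col]].copy()
    out["fold_change"] = (out[median_col] / ref).round(1)
    return out


def group_abeta_table(
    cohort: Sequence[ParticipantRecord], cl_cutoff: float = 25.0
) -> pd.DataFrame:
    """pTau217 medians per (clinical group, amyloid status) stratum."""
    rows = []
    for group in ("CU", "MCI", "dementia"):
        for status, wanted in (("Abeta-", False), ("Abeta+", True)):
            values = [
                r.ptau217
                for r in cohort
                if r.group == group
                and abeta_positive(r.centiloid, cl_cutoff) == wanted
            ]
            rows.append(
                {
                    "stage": f"{group} {status}",
                    "n": len(values),
                    "ptau217_median": float(np.median(values)) if values else np.nan,
                }
            )
    return pd.DataFrame(rows)


# --- internal helpers -----------------------------------------------------


def _subgroup_mask(records: Sequence[ParticipantRecord], name: str) -> np.ndarray:
    if name == "all":
        return np.ones(len(records), dtype=bool)
    if name == "CU":
        return np.array([r.group == "CU" for r in records])
    if name == "CI":
        return np.array([r.group in ("MCI", "dementia") for r in records])
    raise ValueError(f"unknown subgroup {name!r}")


def _roc_row(
    scores: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    B: int,
    level: float,
) -> dict:
    """AUC, Youden operating point and bootstrap CIs for one ROC analysis.

    One joint bootstrap pass re-derives the ROC and its Youden point per
    replicate, so the threshold CI reflects threshold re-estimation.
    """
    roc = ev.roc_curve(scores, labels)
    point = ev.youden_point(roc)

    def _stats(s: np.ndarray, l: np.ndarray) -> np.ndarray:
        r = ev.roc_curve(s, l)
        pt = ev.youden_point(r)
        return np.array(
            [
                r.auc,
                pt.threshold,
                pt.sens,
                pt.spec,
                np.nan if pt.ppv is None else pt.ppv,
                np.nan if pt.npv is None else pt.npv,
                pt.accuracy,
            ]
        )

    n = scores.size
    reps = np.full((B, 7), np.nan)
    for b in range(B):
        for _ in range(10):
            idx = rng.integers(0, n, size=n)
            l = labels[idx]
            if l.min() != l.max():
                reps[b] = _stats(scores[idx], l)
                break
    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanpercentile(reps, 100 * alpha, axis=0)
        hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    names = ("auc", "youden_threshold", "sens", "spec", "ppv", "npv", "accuracy")
    values = (
        roc.auc, point.threshold, point.sens, point.spec,
        point.ppv, point.npv, point.accuracy,
    )
    row: dict = {"n": int(n), "n_pos": int(roc.n_pos)}
    for i, (name, value) in enumerate(zip(names, values)):
        row[name] = np.nan if value is None else float(value)
        row[f"{name}_lo"] = float(lo[i])
        row[f"{name}_hi"] = float(hi[i])
    return row


def _model_features(
    staged: pd.DataFrame, cohort: Sequence[ParticipantRecord]
) -> pd.DataFrame:
    by_id = {r.id: r for r in cohort}
    frame = staged[["id", "biological_stage", "ptau217"]].copy()
    frame["age"] = [by_id[i].age for i in frame["id"]]
    frame["male"] = [1.0 if by_id[i].sex == "male" else 0.0 for i in frame["id"]]
    frame["apoe4"] = [1.0 if by_id[i].apoe4 else 0.0 for i in frame["id"]]
    frame["group"] = [by_id[i].group for i in frame["id"]]
    return frame


def run_analysis(
    cohort: Sequence[ParticipantRecord] | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the full analysis over a cohort (records or a cohort CSV path)."""
    config = config or AnalysisConfig()
    if isinstance(cohort, (str, Path)):
        cohort = read_cohort_csv(str(cohort))
    if not cohort:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(7,))
    )
    B, level = config.bootstrap_b, config.level

    thresholds = build_threshold_set(
        cohort,
        method=config.tau_method,
        k=config.k,
        p=config.p,
        centiloid_cutoff=config.cl_cutoff,
        te_high=config.te_high_mode if isinstance(config.te_high_mode, str) else float(config.te_high_mode),
    )
    thresholds_p95 = build_threshold_set(
        cohort,
        method="percentile",
        p=95.0,
        centiloid_cutoff=config.cl_cutoff,
        te_high=thresholds.te_high_cutoff,
    )
    staged = stage_cohort(cohort, thresholds)

    ptau = np.array([r.ptau217 for r in cohort])
    centiloid = np.array([r.centiloid for r in cohort])
    composites = [composite_values(r) for r in cohort]

    # correlations: pTau217 vs Centiloid and tau composite SUVR, per subgroup
    corr_rows = []
    targets = {
        "centiloid": centiloid,
        "suvr_Me": np.array([c["Me"] for c in composites]),
        "suvr_Te": np.array([c["Te"] for c in composites]),
        "suvr_MetaT": np.array([c["MetaT"] for c in composites]),
    }
    for subgroup in config.subgroups:
        mask = _subgroup_mask(cohort, subgroup)
        if mask.sum() < 3:
            log.warning("subgroup %s has <3 records; correlations skipped", subgroup)
            continue
        for target_name, values in targets.items():
            res = ev.spearman(
                ptau[mask], values[mask], B=B, level=level, rng=rng
            )
            p_raw = float(sps.spearmanr(ptau[mask], values[mask]).pvalue)
            corr_rows.append(
                {
                    "subgroup": subgroup,
                    "target": target_name,
                    "n": res.n,
                    "r": res.r,
                    "r_lo": res.ci[0],
                    "r_hi": res.ci[1],
                    "p": p_raw,
                }
            )
    correlations = pd.DataFrame(corr_rows)
    if not correlations.empty:
        correlations["p_adj"] = ev.bonferroni(correlations["p"].to_numpy())

    # ROC suites
    roc_rows = []
    sweep = config.cl_sweep or (config.cl_cutoff,)
    for cl in sweep:
        abeta = np.array([abeta_positive(c, cl) for c in centiloid])
        subgroups = config.subgroups if cl == config.cl_cutoff else ("all",)
        for subgroup in subgroups:
            mask = _subgroup_mask(cohort, subgroup)
            labels = abeta[mask]
            if labels.size == 0 or labels.min() == labels.max():
                log.warning(
                    "ROC Abeta@%.0f CL skipped for subgroup %s (degenerate labels)",
                    cl, subgroup,
                )
                continue
            row = {
                "subgroup": subgroup,
                "outcome": "Abeta",
                "rule": f"CL>={cl:g}",
                **_roc_row(ptau[mask], labels.astype(int), rng, B, level),
            }
            roc_rows.append(row)
    for roi in ("Me", "Te", "MetaT"):
        for ts, rule in ((thresholds, "mean+2.5SD"), (thresholds_p95, "p95")):
            suvr = np.array([c[roi] for c in composites])
            labels = (suvr > ts.tau_cutoffs[roi]).astype(int)
            if labels.min() == labels.max():
                log.warning("ROC tau %s (%s) skipped (degenerate labels)", roi, rule)
                continue
            roc_rows.append(
                {
                    "subgroup": "all",
                    "outcome": f"Tau{roi}",
                    "rule": rule,
                    **_roc_row(ptau, labels, rng, B, level),
                }
            )
    braak_ok = staged["braak_dichotomy"] != "Atypical"
    for subgroup in ("all", "CI"):
        mask = _subgroup_mask(cohort, subgroup) & braak_ok.to_numpy()
        labels = (staged.loc[mask, "braak_dichotomy"] == "high").to_numpy().astype(int)
        if labels.size == 0 or labels.min() == labels.max():
            log.warning("Braak dichotomy ROC skipped for subgroup %s", subgroup)
            continue
        roc_rows.append(
            {
                "subgroup": subgroup,
                "outcome": "BraakIV-VI",
                "rule": "mean+2.5SD",
                **_roc_row(ptau[mask], labels, rng, B, level),
            }
        )
    roc_summary = pd.DataFrame(roc_rows)

    # two-threshold triage for amyloid status
    zone_rows = []
    abeta = np.array(
        [abeta_positive(c, config.cl_cutoff) for c in centiloid]
    ).astype(int)
    if abeta.min() != abeta.max():
        roc_all = ev.roc_curve(ptau, abeta)
        for sens_t, spec_t in config.zone_targets:
            lower = ev.threshold_at_sensitivity(roc_all, sens_t).threshold
            try:
                upper = ev.threshold_at_specificity(roc_all, spec_t).threshold
            except ValueError as exc:
                log.warning("zone pair (%s, %s) skipped: %s", sens_t, spec_t, exc)
                continue
            collapsed = lower > upper
            if collapsed:
                # the targets cross (separation is strong enough that the
                # high-sensitivity cutoff already exceeds the
                # high-specificity one): no indeterminate zone is feasible,
                # fall back to the single Youden threshold
                lower = upper = ev.youden_point(roc_all).threshold
                log.warning(
                    "zone pair (%s, %s): thresholds cross; collapsed to the "
                    "Youden threshold %.4g", sens_t, spec_t, lower,
                )
            zc = ev.two_threshold_classify(ptau, abeta, lower, upper)
            zone_rows.append(
                {
                    "sens_target": sens_t,
                    "spec_target": spec_t,
                    "lower": zc.lower,
                    "upper": zc.upper,
                    "collapsed": collapsed,
                    "frac_low": zc.frac_low,
                    "frac_ind": zc.frac_ind,
                    "frac_high": zc.frac_high,
                    "pct_low_correct": zc.pct_low_correct,
                    "pct_high_correct": zc.pct_high_correct,
                    "overall_correct": zc.overall_correct,
                }
            )
    else:
        log.warning("triage skipped: single amyloid class")
    zones = pd.DataFrame(zone_rows)

    # logistic stage-discrimination models
    features = _model_features(staged, cohort)
    model_rows = []
    for subgroup in ("all", "CI"):
        mask = _subgroup_mask(cohort, subgroup)
        sub = features[mask & (features["biological_stage"] != "Atypical").to_numpy()]
        sub = sub.dropna(subset=["ptau217", "age", "male", "apoe4"])
        dropped = int((mask & (features["biological_stage"] != "Atypical").to_numpy()).sum() - len(sub))
        if dropped:
            log.warning("%d records dropped from %s models (missing covariates)",
                        dropped, subgroup)
        for contrast, positive_stages in _CONTRASTS.items():
            y = sub["biological_stage"].isin(positive_stages).to_numpy().astype(int)
            if y.size < 10 or y.min() == y.max():
                log.warning("stage model %s skipped for subgroup %s", contrast, subgroup)
                continue
            designs = {
                "ptau": sub[["ptau217"]].to_numpy(),
                "base": sub[["age", "male", "apoe4"]].to_numpy(),
                "full": sub[["ptau217", "age", "male", "apoe4"]].to_numpy(),
            }
            predicted = {}
            for model, X in designs.items():
                try:
                    fit = ev.fit_logistic(X, y)
                except ValueError as exc:
                    log.warning(
                        "stage model %s/%s (%s) skipped: %s",
                        subgroup, contrast, model, exc,
                    )
                    continue
                predicted[model] = fit.predicted
                roc = ev.roc_curve(fit.predicted, y)
                ci = ev.bootstrap_ci(
                    lambda s, l: ev.roc_curve(s, l).auc,
                    (fit.predicted, y),
                    B=B,
                    level=level,
                    rng=rng,
                )
                model_rows.append(
                    {
                        "subgroup": subgroup,
                        "contrast": contrast,
                        "model": model,
                        "n": int(y.size),
                        "n_pos": int(y.sum()),
                        "auc": roc.auc,
                        "auc_lo": ci[0],
                        "auc_hi": ci[1],
                        "separation": fit.separation,
                    }
                )
            for other in ("base", "full"):
                if "ptau" not in predicted or other not in predicted:
                    continue
                cmp = ev.delong_compare(predicted["ptau"], predicted[other], y)
                model_rows.append(
                    {
                        "subgroup": subgroup,
                        "contrast": contrast,
                        "model": f"ptau vs {other}",
                        "n": int(y.size),
                        "n_pos": int(y.sum()),
                        "auc": cmp.auc_a - cmp.auc_b,
                        "delong_z": cmp.z,
                        "delong_p": cmp.p,
                    }
                )
    stage_models = pd.DataFrame(model_rows)
    if not stage_models.empty and "delong_p" in stage_models.columns:
        is_test = stage_models["delong_p"].notna()
        for subgroup in stage_models.loc[is_test, "subgroup"].unique():
            fam = is_test & (stage_models["subgroup"] == subgroup)
            stage_models.loc[fam, "delong_p_adj"] = ev.bonferroni(
                stage_models.loc[fam, "delong_p"].to_numpy()
            )

    stage_medians = stage_table(cohort, thresholds, by="biological")
    braak_medians = stage_table(cohort, thresholds, by="braak", merge_braak_ii=True)
    prevalence = prevalence_summary(cohort, config.cl_cutoff)
    fold_changes = fold_change_summary(
        group_abeta_table(cohort, config.cl_cutoff), reference="CU Abeta-"
    )

    metadata = {
        "n_records": len(cohort),
        "seed": config.seed,
        "config_hash": config.hash(),
        "bootstrap_b": B,
        "cl_cutoff": config.cl_cutoff,
    }
    bundle = ReportBundle(
        thresholds=thresholds,
        staging=staged,
        correlations=correlations,
        roc_summary=roc_summary,
        zones=zones,
        stage_models=stage_models,
        stage_medians=stage_medians,
        braak_medians=braak_medians,
        prevalence=prevalence,
        fold_changes=fold_changes,
        metadata=metadata,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
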