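"""PET-based Braak staging and amyloid-tau biological staging.

Braak staging thresholds each of the six Braak composites and assigns the
"latest" positive composite provided all earlier composites are also
positive; out-of-order profiles are Atypical.  Stages are additionally
grouped (I-II / III-IV / V-VI) and dichotomised (low 0-III vs high IV-VI).

Biological staging combines amyloid status with the topographic extent and
magnitude of tau: A-T- (amyloid negative, tau negative in all quantification
ROIs), Initial (A+T-), Early (A+, tau limited to the mesial-temporal Me
composite), Intermediate (A+, moderate temporoparietal tau) and Advanced
(A+, high temporoparietal tau, Te SUVR above the moderate/high boundary).
Records fitting none of the five criteria -- amyloid-negative tau-positive
profiles, or amyloid-positive profiles with rest-of-neocortex but no
temporoparietal tau -- are Atypical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord
from .composites import BRAAK_COMPOSITES
from .thresholds import ThresholdSet, abeta_positive, composite_values

__all__ = [
    "BRAAK_STAGES",
    "BIOLOGICAL_LABELS",
    "TauProfile",
    "BraakAssignment",
    "BiologicalStage",
    "tau_profile",
    "assign_braak",
    "assign_biological",
    "stage_cohort",
    "stage_table",
]

BRAAK_STAGES: tuple[str, ...] = ("0", "I", "II", "III", "IV", "V", "VI")
BIOLOGICAL_LABELS: tuple[str, ...] = (
    "A-T-",
    "Initial",
    "Early",
    "Intermediate",
    "Advanced",
    "Atypical",
)


@dataclass(frozen=True)
class TauProfile:
    """Per-participant tau positivity bits and the Te composite SUVR."""

    positivity: tuple[bool, bool, bool, bool, bool, bool]
    me_pos: bool
    te_pos: bool
    r_pos: bool
    te_suvr: float

    def __post_init__(self) -> None:
        if len(self.positivity) != 6:
            raise ValueError(
                f"positivity must have exactly 6 Braak entries, "
                f"got {len(self.positivity)}"
            )


@dataclass(frozen=True)
class BraakAssignment:
    """Braak stage with its grouped and dichotomised forms."""

    stage: str  # "0", "I".."VI" or "Atypical"
    grouped: str  # "0", "I-II", "III-IV", "V-VI" or "Atypical"
    dichotomy: str  # "low" (0-III), "high" (IV-VI) or "Atypical"


@dataclass(frozen=True)
class BiologicalStage:
    label: str  # one of BIOLOGICAL_LABELS
    abeta_pos: bool


def tau_profile(record: ParticipantRecord, thresholds: ThresholdSet) -> TauProfile:
    """Threshold every composite; positivity is strictly SUVR > cutoff."""
    values = composite_values(record)
    missing = [
        name
        for name in (*BRAAK_COMPOSITES, "Me", "Te", "R")
        if name not in thresholds.tau_cutoffs
    ]
    if missing:
        raise KeyError(f"threshold set lacks cutoffs for composites: {missing}")
    positivity = tuple(
        bool(values[name] > thresholds.tau_cutoffs[name]) for name in BRAAK_COMPOSITES
    )
    return TauProfile(
        positivity=positivity,  # type: ignore[arg-type]
        me_pos=bool(values["Me"] > thresholds.tau_cutoffs["Me"]),
        te_pos=bool(values["Te"] > thresholds.tau_cutoffs["Te"]),
        r_pos=bool(values["R"] > thresholds.tau_cutoffs["R"]),
        te_suvr=values["Te"],
    )


def _group_stage(stage: str) -> str:
    if stage == "Atypical" or stage == "0":
        return stage
    if stage in ("I", "II"):
        return "I-II"
    if stage in ("III", "IV"):
        return "III-IV"
    return "V-VI"


def _dichotomise(stage: str) -> str:
    if stage == "Atypical":
        return "Atypical"
    return "low" if stage in ("0", "I", "II", "III") else "high"


def assign_braak(profile: TauProfile) -> BraakAssignment:
    """Latest-positive-composite rule; non-prefix patterns are Atypical."""
    bits = profile.positivity
    n_pos = sum(bits)
    is_prefix = all(bits[:n_pos]) and not any(bits[n_pos:])
    stage = BRAAK_STAGES[n_pos] if is_prefix else "Atypical"
    return BraakAssignment(
        stage=stage, grouped=_group_stage(stage), dichotomy=_dichotomise(stage)
    )


def assign_biological(
    record: ParticipantRecord, profile: TauProfile, thresholds: ThresholdSet
) -> BiologicalStage:
    """Amyloid-tau biological stage from a tau profile and Centiloid value.

    Moderate tau is operationalised as Te-positive with Te SUVR at or below
    the moderate/high boundary, regardless of Me/R status; high tau is Te
    SUVR above the boundary.  Amyloid-negative tau-positive records are
    Atypical.
    """
    abeta = abeta_positive(record.centiloid, thresholds.centiloid_cutoff)
    tau_negative = not (profile.me_pos or profile.te_pos or profile.r_pos)
    if not abeta:
        label = "A-T-" if tau_negative else "Atypical"
    elif tau_negative:
        label = "Initial"
    elif profile.te_suvr > thresholds.te_high_cutoff:
        label = "Advanced"
    elif profile.te_pos:
        label = "Intermediate"
    elif profile.me_pos and not profile.r_pos:
        label = "Early"
    else:
        label = "Atypical"
    return BiologicalStage(label=label, abeta_pos=abeta)


def stage_cohort(
    cohort: Sequence[ParticipantRecord], thresholds: ThresholdSet
) -> pd.DataFrame:
    """Stage every record; one row per participant.

    Columns: id, the six Braak positivity bits, Me/Te/R positivity,
    te_suvr, braak_stage / braak_grouped / braak_dichotomy,
    biological_stage, abeta_pos and ptau217.
    """
    rows = []
    for record in cohort:
        profile = tau_profile(record, thresholds)
        braak = assign_braak(profile)
        biological = assign_biological(record, profile, thresholds)
        row = {
            "id": record.id,
            "group": record.group,
            "ptau217": record.ptau217,
            "centiloid": record.centiloid,
            "abeta_pos": biological.abeta_pos,
            **{
                f"pos_{name}": bit
                for name, bit in zip(BRAAK_COMPOSITES, profile.positivity)
            },
            "pos_Me": profile.me_pos,
            "pos_Te": profile.te_pos,
            "pos_R": profile.r_pos,
            "te_suvr": profile.te_suvr,
            "braak_stage": braak.stage,
            "braak_grouped": braak.grouped,
            "braak_dichotomy": braak.dichotomy,
            "biological_stage": biological.label,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def stage_table(
    cohort: Sequence[ParticipantRecord],
    thresholds: ThresholdSet,
    by: str = "biological",
    merge_braak_ii: bool = False,
) -> pd.DataFrame:
    """Per-stage counts with pTau217 median and IQR.

    ``by`` is ``"biological"`` or ``"braak"``.  ``merge_braak_ii`` reports
    Braak I and II as one "I-II" row (a reporting-level convenience for
    sparse stage II); staging itself always keeps II distinct.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    staged = stage_cohort(cohort, thresholds)
    if by == "biological":
        order = list(BIOLOGICAL_LABELS)
        column = "biological_stage"
    elif by == "braak":
        column = "braak_stage"
        order = list(BRAAK_STAGES) + ["Atypical"]
        if merge_braak_ii:
            staged = staged.copy()
            staged[column] = staged[column].replace({"I": "I-II", "II": "I-II"})
            order = ["0", "I-II", "III", "IV", "V", "VI", "Atypical"]
    else:
        raise ValueError(f"unknown stage axis {by!r}")
    rows = []
    for stage in order:
        values = staged.loc[staged[column] == stage, "ptau217"].to_numpy()
        rows.append(
            {
                "stage": stage,
                "n": int(values.size),
                "ptau217_median": float(np.median(values)) if values.size else np.nan,
                "ptau217_q1": float(np.percentile(values, 25)) if values.size else np.nan,
                "ptau217_q3": float(np.percentile(values, 75)) if values.size else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    assert int(table["n"].sum()) == len(cohort), "stage categories must partition"
    return table
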