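"""Synthetic cohort generation for plasma pTau217 vs amyloid/tau PET analyses.

The generator emulates a cross-sectional memory-clinic research cohort in
which every participant has a clinical classification (CU / MCI / dementia),
an amyloid-PET Centiloid value, regional tau-PET SUVR values over a
Desikan-Killiany-style atlas, and a plasma pTau217 concentration.

The generative model is hierarchical, mirroring the staging logic the
analysis applies downstream so that truth labels exist for recovery tests:

    clinical group -> amyloid status -> biological AD stage
        -> (Centiloid, true Braak stage, regional SUVRs, pTau217)

* Centiloid for amyloid-negative strata is a truncated normal centred near
  zero; amyloid-positive strata use a shifted log-normal matched to the
  per-group medians of typical research cohorts.
* pTau217 is log-normal with a stage-specific median (concentrations are
  positive and right-skewed).
* Regional tau SUVR profiles follow the Braak prefix order: a participant
  with true Braak stage k has every region belonging to Braak composites
  I..k elevated and all later regions at baseline, except for a
  configurable fraction of deliberately out-of-order ("atypical") profiles.

Rejection sampling guarantees each record is internally consistent: its
composite SUVRs reproduce the intended Braak prefix and biological stage
when thresholded at the design cutoffs (baseline mean + 2.5 composite SD),
with a safety margin of one composite SD on either side so that cutoffs
re-derived empirically from the cohort classify the record identically
with high probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .composites import (
    BRAAK_COMPOSITES,
    builtin_definitions,
    all_required_regions,
    compose_suvr,
)

__all__ = [
    "GROUPS",
    "BIOLOGICAL_STAGES",
    "TE_HIGH",
    "CohortConfig",
    "ParticipantRecord",
    "default_config",
    "generate_cohort",
    "design_cutoffs",
    "calibration_report",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUPS: tuple[str, ...] = ("CU", "MCI", "dementia")
BIOLOGICAL_STAGES: tuple[str, ...] = (
    "A-T-",
    "Initial",
    "Early",
    "Intermediate",
    "Advanced",
)

#: Temporoparietal SUVR boundary between moderate and high tau burden used
#: as ground truth when generating Intermediate vs Advanced profiles
#: (upper-quartile-derived boundary reported for MK6240).
TE_HIGH: float = 2.68

# --- generator design constants (not part of the public config surface) ---

#: Distribution of the true Braak stage conditional on biological stage.
#: Tau-negative stages are Braak 0; mesial-only tau sits at Braak II-III;
#: moderate neocortical tau at IV-V; high neocortical tau at V-VI.
_BRAAK_MIX: dict[str, tuple[tuple[int, float], ...]] = {
    "A-T-": ((0, 1.0),),
    "Initial": ((0, 1.0),),
    "Early": ((2, 0.25), (3, 0.75)),
    "Intermediate": ((4, 0.5), (5, 0.5)),
    "Advanced": ((5, 0.4), (6, 0.6)),
}

#: Regions whose tau elevation is damped relative to the participant's
#: neocortical magnitude (MK6240 mesial-temporal signal runs lower than
#: neocortical signal at matched stage).
_DAMPED_REGIONS = frozenset(
    {"entorhinal", "hippocampus", "parahippocampal", "amygdala", "fusiform"}
)
_DAMPING = 0.6

#: Earliest Braak composite each atlas region belongs to; regions outside
#: the Braak lists (angular and the rest-of-neocortex composite members)
#: are assigned by anatomical analogy to their neighbours.
_EXTRA_REGION_STAGE = {
    "angular": 5,
    "dorsolateral_prefrontal": 5,
    "ventrolateral_prefrontal": 5,
    "orbitofrontal": 5,
    "gyrus_rectus": 5,
    "anterior_cingulate": 4,
}

#: Rejection-sampling margins in units of the composite's design SD:
#: baseline composites must sit at least this far below the design cutoff,
#: elevated composites at least this far above.
_BASELINE_MARGIN = 1.5
_ELEVATED_MARGIN = 1.0
#: Absolute SUVR margin around the moderate/high Te boundary.
_TE_HIGH_MARGIN = 0.03
_MAX_ATTEMPTS = 500


def _region_stage_map() -> dict[str, int]:
    registry = builtin_definitions()
    stage_of: dict[str, int] = {}
    for idx, name in enumerate(BRAAK_COMPOSITES, start=1):
        for region in registry[name].regions:
            stage_of.setdefault(region, idx)
    stage_of.update(_EXTRA_REGION_STAGE)
    missing = all_required_regions() - set(stage_of)
    if missing:  # pragma: no cover - registry/map drift guard
        raise RuntimeError(f"regions without a stage assignment: {sorted(missing)}")
    return stage_of


_REGION_STAGE = _region_stage_map()
_ALL_REGIONS: tuple[str, ...] = tuple(sorted(all_required_regions()))


@dataclass
class ParticipantRecord:
    """One participant's clinical labels, PET measures and plasma pTau217.

    ``truth`` is carried only by synthetic records and holds the generating
    labels: biological stage, amyloid status and true Braak stage.
    """

    id: str
    group: str
    age: float
    sex: str
    apoe4: bool
    centiloid: float
    regional_suvr: dict[str, float]
    ptau217: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.ptau217 > 0:
            raise ValueError(f"ptau217 must be > 0, got {self.ptau217}")
        for region, value in self.regional_suvr.items():
            if not value > 0:
                raise ValueError(f"SUVR for region {region!r} must be > 0, got {value}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions of a 388-participant research
    cohort: group sizes 156/100/132 (CU/MCI/dementia), amyloid-PET
    positivity prevalence 0.40/0.69/0.89, per-stratum Centiloid mixtures,
    biological-stage mixes among amyloid-positive participants, and
    stage-wise pTau217 medians 0.1/0.2/0.4/0.6/0.9 pg/ml.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CU": 156, "MCI": 100, "dementia": 132}
    )
    abeta_prevalence: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.40, "MCI": 0.69, "dementia": 0.89}
    )
    centiloid_params: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "CU": {
                "neg": {"loc": -0.3, "scale": 8.0},
                "pos": {"median": 79.3, "sigma": 0.70},
            },
            "MCI": {
                "neg": {"loc": -0.9, "scale": 8.0},
                "pos": {"median": 113.0, "sigma": 0.45},
            },
            "dementia": {
                "neg": {"loc": 2.5, "scale": 8.0},
                "pos": {"median": 113.4, "sigma": 0.45},
            },
        }
    )
    stage_mix: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "CU": {
                "neg": {"A-T-": 1.0},
                "pos": {
                    "Initial": 0.855,
                    "Early": 0.032,
                    "Intermediate": 0.097,
                    "Advanced": 0.016,
                },
            },
            "MCI": {
                "neg": {"A-T-": 1.0},
                "pos": {
                    "Initial": 0.232,
                    "Early": 0.070,
                    "Intermediate": 0.395,
                    "Advanced": 0.303,
                },
            },
            "dementia": {
                "neg": {"A-T-": 1.0},
                "pos": {
                    "Initial": 0.232,
                    "Early": 0.070,
                    "Intermediate": 0.395,
                    "Advanced": 0.303,
                },
            },
        }
    )
    ptau_stage_medians: dict[str, float] = field(
        default_factory=lambda: {
            "A-T-": 0.1,
            "Initial": 0.2,
            "Early": 0.4,
            "Intermediate": 0.6,
            "Advanced": 0.9,
        }
    )
    ptau_log_sd: float = 0.35
    suvr_baseline: dict[str, float] = field(
        default_factory=lambda: {"mean": 1.0, "sd": 0.05}
    )
    suvr_increment: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A-T-": (0.0, 0.0),
            "Initial": (0.0, 0.0),
            "Early": (0.3, 0.5),
            "Intermediate": (0.45, 1.65),
            "Advanced": (2.0, 3.4),
        }
    )
    atypical_rate: float = 0.09
    covariate_params: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "CU": {
                "neg": {"age_mean": 74.7, "age_sd": 4.7, "male": 0.51, "apoe4": 0.24},
                "pos": {"age_mean": 76.2, "age_sd": 6.6, "male": 0.47, "apoe4": 0.56},
            },
            "MCI": {
                "neg": {"age_mean": 69.6, "age_sd": 8.2, "male": 0.48, "apoe4": 0.29},
                "pos": {"age_mean": 75.5, "age_sd": 6.9, "male": 0.59, "apoe4": 0.72},
            },
            "dementia": {
                "neg": {"age_mean": 71.4, "age_sd": 6.6, "male": 0.67, "apoe4": 0.13},
                "pos": {"age_mean": 70.0, "age_sd": 7.9, "male": 0.50, "apoe4": 0.74},
            },
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for group in GROUPS:
            if group not in self.n_per_group:
                raise ValueError(f"n_per_group: missing group {group!r}")
            if self.n_per_group[group] < 1:
                raise ValueError(
                    f"n_per_group[{group!r}] must be >= 1, "
                    f"got {self.n_per_group[group]}"
                )
            prevalence = self.abeta_prevalence.get(group)
            if prevalence is None or not 0.0 <= prevalence <= 1.0:
                raise ValueError(
                    f"abeta_prevalence[{group!r}] must be in [0, 1], got {prevalence}"
                )
            for status in ("neg", "pos"):
                mix = self.stage_mix.get(group, {}).get(status)
                if not mix:
                    raise ValueError(f"stage_mix[{group!r}][{status!r}] missing")
                if any(not 0.0 <= p <= 1.0 for p in mix.values()):
                    raise ValueError(
                        f"stage_mix[{group!r}][{status!r}]: probabilities "
                        "must be in [0, 1]"
                    )
                if abs(sum(mix.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"stage_mix[{group!r}][{status!r}] must sum to 1, "
                        f"got {sum(mix.values())!r}"
                    )
                if any(stage not in BIOLOGICAL_STAGES for stage in mix):
                    raise ValueError(
                        f"stage_mix[{group!r}][{status!r}]: unknown stage key"
                    )
        medians = [self.ptau_stage_medians[s] for s in BIOLOGICAL_STAGES]
        if any(m <= 0 for m in medians):
            raise ValueError("ptau_stage_medians: medians must be positive")
        if any(b <= a for a, b in zip(medians, medians[1:])):
            raise ValueError(
                "ptau_stage_medians must be strictly increasing across "
                f"ordered stages, got {medians}"
            )
        if not self.ptau_log_sd > 0:
            raise ValueError(f"ptau_log_sd must be > 0, got {self.ptau_log_sd}")
        if not 0.0 <= self.atypical_rate <= 1.0:
            raise ValueError(
                f"atypical_rate must be in [0, 1], got {self.atypical_rate}"
            )
        if not self.suvr_baseline["sd"] > 0 or not self.suvr_baseline["mean"] > 0:
            raise ValueError("suvr_baseline: mean and sd must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        base = cls()
        kwargs = {}
        for key in base.__dataclass_fields__:
            if key in data:
                value = data[key]
                if key == "suvr_increment":
                    value = {k: tuple(v) for k, v in value.items()}
                kwargs[key] = value
            else:
                kwargs[key] = getattr(base, key)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "CohortConfig":
        """Load a config from JSON or YAML mirroring the field names."""
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_dict(data)


def default_config(seed: int = 0) -> CohortConfig:
    """The study-conditions configuration with the given RNG seed."""
    return CohortConfig(seed=seed)


def design_cutoffs(config: CohortConfig) -> dict[str, float]:
    """Design tau-positivity cutoffs implied by the baseline SUVR model.

    For a composite of ``r`` independent baseline regions the composite SD
    is ``sd / sqrt(r)``; the cutoff is baseline mean + 2.5 composite SD,
    matching the reference-population rule the analysis applies.
    """
    mean = config.suvr_baseline["mean"]
    sd = config.suvr_baseline["sd"]
    return {
        name: mean + 2.5 * sd / math.sqrt(len(definition.regions))
        for name, definition in builtin_definitions().items()
    }


def _composite_sd(config: CohortConfig, name: str) -> float:
    regions = builtin_definitions()[name].regions
    return config.suvr_baseline["sd"] / math.sqrt(len(regions))


def _draw_categorical(rng: np.random.Generator, pmf: Mapping[str, float]) -> str:
    keys = list(pmf)
    probs = np.array([pmf[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_centiloid(
    rng: np.random.Generator, params: Mapping[str, float], positive: bool
) -> float:
    if positive:
        mu = math.log(params["median"] - 25.0)
        return 25.0 + rng.lognormal(mean=mu, sigma=params["sigma"])
    # truncated normal on [-10, 25); simple rejection
    for _ in range(1000):
        value = rng.normal(params["loc"], params["scale"])
        if -10.0 <= value < 25.0:
            return value
    raise RuntimeError("centiloid rejection sampling failed")  # pragma: no cover


def _profile_constraints(
    stage: str, braak_k: int, flip: int | None
) -> dict[str, str]:
    """Which composites must be above/below their design cutoff.

    Returns a map composite -> 'elevated' | 'baseline' | 'te_moderate' |
    'te_high' (the Te entries additionally constrain the moderate/high
    boundary).  Unlisted composites are unconstrained.
    """
    constraints: dict[str, str] = {}
    for idx, name in enumerate(BRAAK_COMPOSITES, start=1):
        expected = idx <= braak_k and idx != flip
        constraints[name] = "elevated" if expected else "baseline"
    if stage in ("A-T-", "Initial"):
        constraints.update({"Me": "baseline", "Te": "baseline", "R": "baseline"})
    elif stage == "Early":
        constraints.update({"Me": "elevated", "Te": "baseline", "R": "baseline"})
    elif stage == "Intermediate":
        constraints["Te"] = "te_moderate"
    elif stage == "Advanced":
        constraints["Te"] = "te_high"
    return constraints


def _check_profile(
    composites: Mapping[str, float],
    constraints: Mapping[str, str],
    cutoffs: Mapping[str, float],
    sds: Mapping[str, float],
) -> bool:
    for name, kind in constraints.items():
        value = composites[name]
        cutoff, sd = cutoffs[name], sds[name]
        if kind == "baseline":
            if value > cutoff - _BASELINE_MARGIN * sd:
                return False
        elif kind == "elevated":
            if value < cutoff + _ELEVATED_MARGIN * sd:
                return False
        elif kind == "te_moderate":
            if value < cutoff + _ELEVATED_MARGIN * sd:
                return False
            if value > TE_HIGH - _TE_HIGH_MARGIN:
                return False
        elif kind == "te_high":
            if value < TE_HIGH + _TE_HIGH_MARGIN:
                return False
    return True


def _draw_suvr_profile(
    rng: np.random.Generator,
    config: CohortConfig,
    stage: str,
    braak_k: int,
    flip: int | None,
    cutoffs: Mapping[str, float],
    sds: Mapping[str, float],
) -> dict[str, float] | None:
    """Rejection-sample a regional SUVR map consistent with the truth labels."""
    registry = builtin_definitions()
    base_mean = config.suvr_baseline["mean"]
    base_sd = config.suvr_baseline["sd"]
    lo, hi = config.suvr_increment[stage]
    constraints = _profile_constraints(stage, braak_k, flip)
    for _ in range(_MAX_ATTEMPTS):
        magnitude = rng.uniform(lo, hi) if hi > 0 else 0.0
        values: dict[str, float] = {}
        for region in _ALL_REGIONS:
            stage_of = _REGION_STAGE[region]
            elevated = stage_of <= braak_k and stage_of != flip
            weight = _DAMPING if region in _DAMPED_REGIONS else 1.0
            value = base_mean + (weight * magnitude if elevated else 0.0)
            value += rng.normal(0.0, base_sd)
            values[region] = max(value, 0.05)
        composites = {
            name: compose_suvr(values, definition)
            for name, definition in registry.items()
        }
        if _check_profile(composites, constraints, cutoffs, sds):
            return values
    return None


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a synthetic cohort under ``config``.

    Deterministic given ``config.seed``: every participant draws from an
    RNG sub-stream derived from (seed, participant index), so the output is
    independent of generation order and bit-identical across calls.
    """
    config.validate()
    cutoffs = design_cutoffs(config)
    sds = {name: _composite_sd(config, name) for name in cutoffs}
    records: list[ParticipantRecord] = []
    index = 0
    for group in GROUPS:
        for _ in range(config.n_per_group[group]):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
            )
            abeta = bool(rng.random() < config.abeta_prevalence[group])
            status = "pos" if abeta else "neg"
            stage = _draw_categorical(rng, config.stage_mix[group][status])
            braak_k = _draw_categorical(
                rng, {str(k): p for k, p in _BRAAK_MIX[stage]}
            )
            braak_k = int(braak_k)

            flip: int | None = None
            atypical = braak_k >= 3 and rng.random() < config.atypical_rate
            suvr: dict[str, float] | None = None
            if atypical:
                candidates = list(rng.permutation(np.arange(1, braak_k)))
                for candidate in candidates:
                    suvr = _draw_suvr_profile(
                        rng, config, stage, braak_k, int(candidate), cutoffs, sds
                    )
                    if suvr is not None:
                        flip = int(candidate)
                        break
            if suvr is None:
                atypical = False
                flip = None
                suvr = _draw_suvr_profile(
                    rng, config, stage, braak_k, None, cutoffs, sds
                )
            if suvr is None:  # pragma: no cover - margin infeasibility guard
                raise RuntimeError(
                    f"could not generate a consistent SUVR profile for "
                    f"stage={stage} braak={braak_k}"
                )

            ptau = float(
                rng.lognormal(
                    mean=math.log(config.ptau_stage_medians[stage]),
                    sigma=config.ptau_log_sd,
                )
            )
            centiloid = _draw_centiloid(
                rng, config.centiloid_params[group][status], abeta
            )
            cov = config.covariate_params[group][status]
            age = float(np.clip(rng.normal(cov["age_mean"], cov["age_sd"]), 40, 100))
            sex = "male" if rng.random() < cov["male"] else "female"
            apoe4 = bool(rng.random() < cov["apoe4"])

            braak_label = "Atypical" if atypical else (
                "0" if braak_k == 0 else ["I", "II", "III", "IV", "V", "VI"][braak_k - 1]
            )
            records.append(
                ParticipantRecord(
                    id=f"P{index + 1:04d}",
                    group=group,
                    age=round(age, 1),
                    sex=sex,
                    apoe4=apoe4,
                    centiloid=round(centiloid, 2),
                    regional_suvr={k: round(v, 4) for k, v in suvr.items()},
                    ptau217=round(ptau, 4),
                    truth={
                        "stage": stage,
                        "abeta": abeta,
                        "braak": braak_label,
                    },
                )
            )
            index += 1
    return records


# --- calibration report --------------------------------------------------

_BRAAK_LABELS = ("0", "I", "II", "III", "IV", "V", "VI", "Atypical")


def _stratum_mask(cohort: Sequence[ParticipantRecord], key: str) -> np.ndarray:
    token = key.strip()
    if token in BIOLOGICAL_STAGES:
        return np.array([r.truth is not None and r.truth["stage"] == token
                         for r in cohort])
    lowered = token.lower()
    if lowered.startswith("braak"):
        label = token[5:].strip().replace("–", "-")
        if label in _BRAAK_LABELS:
            return np.array(
                [r.truth is not None and r.truth["braak"] == label for r in cohort]
            )
        if "-" in label:
            parts = label.split("-")
            if all(p in _BRAAK_LABELS for p in parts):
                return np.array(
                    [r.truth is not None and r.truth["braak"] in parts
                     for r in cohort]
                )
    raise ValueError(f"unknown stratum key {key!r}")


def calibration_report(
    cohort: Sequence[ParticipantRecord], targets: Mapping[str, float]
) -> pd.DataFrame:
    """Compare generated stratum-wise pTau217 medians against target medians.

    ``targets`` maps a stratum key (a biological stage label such as
    ``"Intermediate"``, or ``"Braak VI"`` / ``"Braak I-II"``) to the target
    median in pg/ml.  Deviation is (generated - target) / target; strata
    with fewer than 5 records are flagged.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    for key, target in targets.items():
        mask = _stratum_mask(cohort, key)
        values = np.array([r.ptau217 for r, m in zip(cohort, mask) if m])
        n = int(values.size)
        generated = float(np.median(values)) if n else float("nan")
        deviation = (generated - target) / target if n else float("nan")
        rows.append(
            {
                "stratum": key,
                "n": n,
                "generated_median": generated,
                "target_median": float(target),
                "relative_deviation": deviation,
                "flagged": n < 5,
            }
        )
    return pd.DataFrame(rows)


# --- cohort CSV I/O -------------------------------------------------------


def cohort_to_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """One row per participant; ``suvr_<region>`` columns, ``truth_`` labels."""
    rows = []
    for r in cohort:
        row: dict = {
            "id": r.id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "apoe4": r.apoe4,
            "centiloid": r.centiloid,
            "ptau217": r.ptau217,
        }
        for region in _ALL_REGIONS:
            row[f"suvr_{region}"] = r.regional_suvr[region]
        if r.truth is not None:
            row["truth_stage"] = r.truth["stage"]
            row["truth_abeta"] = r.truth["abeta"]
            row["truth_braak"] = r.truth["braak"]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Validate and convert a cohort table into participant records.

    Records missing any region required by the built-in composite registry
    are rejected with an itemised error.
    """
    required = {f"suvr_{r}" for r in all_required_regions()}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            "cohort table is missing required SUVR columns: "
            + ", ".join(sorted(missing))
        )
    base_cols = {"id", "group", "age", "sex", "apoe4", "centiloid", "ptau217"}
    missing_base = base_cols - set(frame.columns)
    if missing_base:
        raise ValueError(
            "cohort table is missing required columns: "
            + ", ".join(sorted(missing_base))
        )
    has_truth = {"truth_stage", "truth_abeta", "truth_braak"} <= set(frame.columns)
    records = []
    for _, row in frame.iterrows():
        truth = None
        if has_truth and not pd.isna(row["truth_stage"]):
            truth = {
                "stage": str(row["truth_stage"]),
                "abeta": bool(row["truth_abeta"]),
                "braak": str(row["truth_braak"]),
            }
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                apoe4=bool(row["apoe4"]),
                centiloid=float(row["centiloid"]),
                regional_suvr={
                    c[len("suvr_"):]: float(row[c])
                    for c in frame.columns
                    if c.startswith("suvr_")
                },
                ptau217=float(row["ptau217"]),
                truth=truth,
            )
        )
    return records


def write_cohort_csv(cohort: Sequence[ParticipantRecord], path: str) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str) -> list[ParticipantRecord]:
    return frame_to_cohort(pd.read_csv(path))
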