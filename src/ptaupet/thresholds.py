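"""Derivation of amyloid and tau positivity cutoffs.

Amyloid positivity is Centiloid >= 25 by default (configurable over the
10-50 CL sensitivity range).  Tau positivity per composite ROI is defined
from a reference stratum of amyloid-negative cognitively-unimpaired
participants, either as mean + k*SD (default k = 2.5, sample SD) or as an
upper percentile (default 95th, linear interpolation between order
statistics).  The boundary between moderate and high temporoparietal tau
burden is either fixed at the literature-derived 2.68 SUVR or re-derived
as the upper quartile of the Te composite among amyloid-positive MCI /
dementia participants.

Conventions (documented, configurable where noted): amyloid positivity is
``centiloid >= cutoff``; tau positivity is strictly ``SUVR > cutoff``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .composites import BRAAK_COMPOSITES, builtin_definitions, compose_suvr
from .cohort import ParticipantRecord

__all__ = [
    "ThresholdSet",
    "abeta_positive",
    "composite_values",
    "tau_threshold_mean_sd",
    "tau_threshold_percentile",
    "derive_te_high",
    "build_threshold_set",
]

FIXED_TE_HIGH = 2.68


def abeta_positive(centiloid: float, cutoff: float = 25.0) -> bool:
    """Amyloid-PET positivity: Centiloid at or above the cutoff."""
    return centiloid >= cutoff


def composite_values(
    record: ParticipantRecord | Mapping[str, float]
) -> dict[str, float]:
    """All built-in composite SUVRs for one participant."""
    suvr = record.regional_suvr if isinstance(record, ParticipantRecord) else record
    return {
        name: compose_suvr(suvr, definition)
        for name, definition in builtin_definitions().items()
    }


@dataclass
class ThresholdSet:
    """All positivity cutoffs consumed by staging and evaluation.

    ``tau_cutoffs`` maps composite name -> SUVR cutoff; ``te_high_cutoff``
    is the moderate/high boundary on the Te composite and must not fall
    below the Te positivity cutoff. ``provenance`` records how the set was
    derived (reference stratum sizes, method, parameters).
    """

    tau_cutoffs: dict[str, float]
    centiloid_cutoff: float = 25.0
    tau_method: str = "mean_plus_k_sd"
    k: float | None = 2.5
    p: float | None = None
    te_high_cutoff: float = FIXED_TE_HIGH
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cutoff in self.tau_cutoffs.items():
            if not (math.isfinite(cutoff) and cutoff > 0):
                raise ValueError(f"tau cutoff for {name!r} must be finite and > 0")
        if not math.isfinite(self.centiloid_cutoff):
            raise ValueError("centiloid_cutoff must be finite")
        if "Te" in self.tau_cutoffs and self.te_high_cutoff < self.tau_cutoffs["Te"]:
            raise ValueError(
                f"te_high_cutoff ({self.te_high_cutoff}) must be >= the Te "
                f"positivity cutoff ({self.tau_cutoffs['Te']})"
            )

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ThresholdSet":
        data = json.loads(source)
        return cls(**data)


def tau_threshold_mean_sd(values: Sequence[float], k: float = 2.5) -> float:
    """Reference-population cutoff mean + k * sample SD (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values for mean + k*SD, got {arr.size}")
    return float(arr.mean() + k * arr.std(ddof=1))


def tau_threshold_percentile(values: Sequence[float], p: float = 95.0) -> float:
    """Upper-percentile cutoff, linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least 1 value for a percentile cutoff")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    return float(np.percentile(arr, p, method="linear"))


def derive_te_high(
    cohort: Sequence[ParticipantRecord], centiloid_cutoff: float = 25.0
) -> float:
    """Upper quartile of the Te composite among amyloid-positive MCI/dementia.

    This mirrors the trial-style definition of "high" neocortical tau
    burden as the top quarter of tau-PET results in amyloid-positive
    cognitively impaired participants.
    """
    te = builtin_definitions()["Te"]
    qualifying = [
        compose_suvr(r.regional_suvr, te)
        for r in cohort
        if r.group in ("MCI", "dementia") and abeta_positive(r.centiloid, centiloid_cutoff)
    ]
    if len(qualifying) < 4:
        raise ValueError(
            "need at least 4 amyloid-positive MCI/dementia records to derive "
            f"the high-tau boundary, got {len(qualifying)}"
        )
    return float(np.percentile(qualifying, 75, method="linear"))


def _reference_values(
    cohort: Sequence[ParticipantRecord], centiloid_cutoff: float
) -> list[ParticipantRecord]:
    return [
        r
        for r in cohort
        if r.group == "CU" and not abeta_positive(r.centiloid, centiloid_cutoff)
    ]


def build_threshold_set(
    cohort: Sequence[ParticipantRecord],
    *,
    method: str = "mean_plus_k_sd",
    k: float = 2.5,
    p: float = 95.0,
    centiloid_cutoff: float = 25.0,
    te_high: str | float = "fixed",
    exclude_part: bool = False,
) -> ThresholdSet:
    """Derive tau cutoffs for every built-in composite from the Aβ− CU stratum.

    ``te_high`` selects the moderate/high Te boundary: ``"fixed"`` uses the
    literature value 2.68 SUVR, ``"derive"`` recomputes the upper quartile
    from this cohort, and a float is used verbatim.

    ``exclude_part`` drops amyloid-negative reference participants whose Me
    composite exceeds a provisional Me cutoff (a stand-in rule for primary
    age-related tauopathy) from the Braak-composite reference stratum, then
    recomputes those cutoffs once.  Off by default; this operationalisation
    is this package's, not a published criterion.
    """
    if method not in ("mean_plus_k_sd", "percentile"):
        raise ValueError(f"unknown tau threshold method {method!r}")
    reference = _reference_values(cohort, centiloid_cutoff)
    if len(reference) < 2:
        raise ValueError(
            f"reference stratum (Aβ− CU) has {len(reference)} records; need >= 2"
        )
    composites = [composite_values(r) for r in reference]

    def cutoff_from(values: list[float]) -> float:
        if method == "mean_plus_k_sd":
            return tau_threshold_mean_sd(values, k)
        return tau_threshold_percentile(values, p)

    tau_cutoffs = {
        name: cutoff_from([c[name] for c in composites])
        for name in builtin_definitions()
    }

    n_part = 0
    if exclude_part:
        provisional_me = tau_cutoffs["Me"]
        kept = [
            c for c in composites if c["Me"] <= provisional_me
        ]
        n_part = len(composites) - len(kept)
        if len(kept) >= 2:
            for name in BRAAK_COMPOSITES:
                tau_cutoffs[name] = cutoff_from([c[name] for c in kept])

    if te_high == "fixed":
        te_high_cutoff = FIXED_TE_HIGH
        te_high_mode = "fixed"
    elif te_high == "derive":
        te_high_cutoff = derive_te_high(cohort, centiloid_cutoff)
        te_high_mode = "derived"
    else:
        te_high_cutoff = float(te_high)
        te_high_mode = "explicit"

    provenance = {
        "reference_n": len(reference),
        "part_excluded_n": n_part,
        "method": method,
        "k": k if method == "mean_plus_k_sd" else None,
        "p": p if method == "percentile" else None,
        "centiloid_cutoff": centiloid_cutoff,
        "te_high_mode": te_high_mode,
    }
    return ThresholdSet(
        tau_cutoffs=tau_cutoffs,
        centiloid_cutoff=centiloid_cutoff,
        tau_method=method,
        k=k if method == "mean_plus_k_sd" else None,
        p=p if method == "percentile" else None,
        te_high_cutoff=te_high_cutoff,
        provenance=provenance,
    )
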