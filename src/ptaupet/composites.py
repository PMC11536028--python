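"""Composite tau-PET regions of interest.

Regional MK6240 SUVR values are summarised over composite regions of
interest: the mesial-temporal (Me), temporoparietal (Te), rest-of-neocortex
(R) and meta-temporal (MetaT) composites used for tau quantification, and
the six Braak composites (BraakI..BraakVI) used for topographic tau
staging.  A composite value is the (optionally weighted) mean of its member
regions' SUVR.

Region names are normalised (lower-case, spaces and hyphens to
underscores) before lookup so CSV headers such as ``suvr_Inferior Temporal``
resolve robustly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

__all__ = [
    "CompositeDefinition",
    "normalize_region",
    "builtin_definitions",
    "all_required_regions",
    "compose_suvr",
    "load_definitions",
]


def normalize_region(name: str) -> str:
    """Canonicalise an atlas-region name for dictionary lookup."""
    return name.strip().lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class CompositeDefinition:
    """A named set of atlas regions averaged into one SUVR value.

    Parameters
    ----------
    name:
        Composite name (e.g. ``"Me"``, ``"BraakIV"``).
    regions:
        Ordered member region names; normalised on construction.
    weights:
        Optional non-negative per-region weights; equal weighting when
        omitted.  Must match ``regions`` in length and not be all zero.
    """

    name: str
    regions: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        regions = tuple(normalize_region(r) for r in self.regions)
        object.__setattr__(self, "regions", regions)
        if not regions:
            raise ValueError(f"composite {self.name!r}: regions must be non-empty")
        if len(set(regions)) != len(regions):
            raise ValueError(f"composite {self.name!r}: duplicate region names")
        if self.weights is not None:
            weights = tuple(float(w) for w in self.weights)
            object.__setattr__(self, "weights", weights)
            if len(weights) != len(regions):
                raise ValueError(
                    f"composite {self.name!r}: {len(weights)} weights for "
                    f"{len(regions)} regions"
                )
            if any(w < 0 for w in weights):
                raise ValueError(f"composite {self.name!r}: negative weight")
            if sum(weights) == 0:
                raise ValueError(f"composite {self.name!r}: weights all zero")


# Composite membership. Me/Te/R/MetaT follow the tau-quantification ROI
# scheme (MetaT = Me plus inferior/middle temporal and fusiform); BraakI-VI
# follow the PET adaptation of the neuropathological Braak topography,
# entorhinal cortex through primary sensorimotor/visual cortex.
_BUILTIN_LISTS: dict[str, tuple[str, ...]] = {
    "Me": ("entorhinal", "hippocampus", "parahippocampal", "amygdala"),
    "Te": (
        "inferior_temporal",
        "fusiform",
        "supramarginal",
        "angular",
        "posterior_cingulate",
        "precuneus",
        "superior_parietal",
        "inferior_parietal",
        "lateral_occipital",
    ),
    "R": (
        "dorsolateral_prefrontal",
        "ventrolateral_prefrontal",
        "orbitofrontal",
        "gyrus_rectus",
        "superior_temporal",
        "anterior_cingulate",
    ),
    "MetaT": (
        "entorhinal",
        "hippocampus",
        "parahippocampal",
        "amygdala",
        "inferior_temporal",
        "middle_temporal",
        "fusiform",
    ),
    "BraakI": ("entorhinal",),
    "BraakII": ("hippocampus",),
    "BraakIII": ("parahippocampal", "fusiform", "lingual", "amygdala"),
    "BraakIV": (
        "middle_temporal",
        "thalamus_proper",
        "caudal_anterior_cingulate",
        "rostral_anterior_cingulate",
        "posterior_cingulate",
        "isthmus_cingulate",
        "insula",
        "inferior_temporal",
        "temporal_pole",
    ),
    "BraakV": (
        "superior_frontal",
        "lateral_orbitofrontal",
        "medial_orbitofrontal",
        "frontal_pole",
        "caudal_middle_frontal",
        "rostral_middle_frontal",
        "parsopercularis",
        "parsorbitalis",
        "parstriangularis",
        "caudate",
        "putamen",
        "lateral_occipital",
        "supramarginal",
        "inferior_parietal",
        "superior_parietal",
        "superior_temporal",
        "pallidum",
        "precuneus",
        "bankssts",
        "accumbens",
        "transverse_temporal",
    ),
    "BraakVI": ("pericalcarine", "postcentral", "cuneus", "precentral", "paracentral"),
}

BRAAK_COMPOSITES: tuple[str, ...] = (
    "BraakI",
    "BraakII",
    "BraakIII",
    "BraakIV",
    "BraakV",
    "BraakVI",
)

_BUILTINS: Mapping[str, CompositeDefinition] = MappingProxyType(
    {name: CompositeDefinition(name, regions) for name, regions in _BUILTIN_LISTS.items()}
)


def builtin_definitions() -> Mapping[str, CompositeDefinition]:
    """Return the immutable registry of the 10 built-in composites."""
    return _BUILTINS


def all_required_regions(
    registry: Mapping[str, CompositeDefinition] | None = None,
) -> frozenset[str]:
    """Union of regions referenced by a composite registry (built-ins by default)."""
    registry = _BUILTINS if registry is None else registry
    out: set[str] = set()
    for definition in registry.values():
        out.update(definition.regions)
    return frozenset(out)


def compose_suvr(
    regional_suvr: Mapping[str, float], definition: CompositeDefinition
) -> float:
    """Weighted mean SUVR of a composite's member regions.

    Raises ``KeyError`` naming the missing region and composite, and
    ``ValueError`` on a non-positive SUVR.
    """
    lookup = {normalize_region(k): float(v) for k, v in regional_suvr.items()}
    values = []
    for region in definition.regions:
        if region not in lookup:
            raise KeyError(
                f"region {region!r} required by composite {definition.name!r} "
                "is missing"
            )
        v = lookup[region]
        if not v > 0:
            raise ValueError(
                f"non-positive SUVR {v} for region {region!r} "
                f"(composite {definition.name!r})"
            )
        values.append(v)
    if definition.weights is None:
        return sum(values) / len(values)
    wsum = sum(definition.weights)
    return sum(w * v for w, v in zip(definition.weights, values)) / wsum


def load_definitions(
    path: str, *, allow_override: bool = False
) -> Mapping[str, CompositeDefinition]:
    """Load custom composites from a JSON file ``{name: [regions...]}``.

    Returns a registry of the built-ins extended with the file's entries.
    Redefining a built-in composite requires ``allow_override=True``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    merged = dict(_BUILTINS)
    for name, regions in raw.items():
        if name in _BUILTINS and not allow_override:
            raise ValueError(
                f"composite {name!r} is a built-in; pass allow_override=True "
                "to replace it"
            )
        if isinstance(regions, dict):
            definition = CompositeDefinition(
                name,
                tuple(regions["regions"]),
                tuple(regions["weights"]) if "weights" in regions else None,
            )
        else:
            definition = CompositeDefinition(name, tuple(regions))
        merged[name] = definition
    return MappingProxyType(merged)
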