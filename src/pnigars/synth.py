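"""Synthetic screening cohorts.

Two generators:

* :func:`generate_cohort` draws free-form cohorts from a composition recipe
  (:class:`CohortSpec`): blocks of nodules sharing density type, pathology
  truth and a feature template, with sizes drawn uniformly from a stated
  millimetre range under a seeded generator. Output order and content are
  deterministic given the seed.

* :func:`reconstruct_evaluation_cohort` deterministically rebuilds a
  7,781-nodule surgical cohort (3,018 SN / 1,709 PSN / 3,054 GGN) whose
  classification by both engines reproduces, cell for cell, the per-stratum
  screening contingency tables of the multicenter study the grading system
  was evaluated on. The joint cross-classification of the two systems is
  not published, so the reconstruction fixes one feasible joint per stratum
  — the maximum-concordance one — and records it in
  :data:`RECONSTRUCTION_PLAN`. Any feasible joint has the same per-system
  margins, which is all the downstream statistics consume.

Steering features are minimal and never contradictory: a size-tier choice,
one special sign (lifts a 5-8 mm nodule into a positive grade while staying
under the 6 mm Lung-RADS cut), or satellite lesions (downgrades the grade
one level while Lung-RADS ignores them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .records import (
    BENIGN_FEATURES,
    COURSES,
    DensityType,
    MALIGNANT_SIGNS,
    NoduleRecord,
    PATHOLOGIES,
    validate_record,
)

__all__ = [
    "CohortBlock",
    "CohortSpec",
    "generate_cohort",
    "reconstruct_evaluation_cohort",
    "tag_pathology_subtypes",
    "RECONSTRUCTION_PLAN",
    "GGN_SUBTYPE_COUNTS",
]


@dataclass(frozen=True)
class CohortBlock:
    """A homogeneous block of a cohort recipe.

    ``size_range`` is a (low, high] millimetre interval sampled uniformly and
    rounded to one decimal; a single float fixes the size exactly. For PSNs,
    ``solid_range`` does the same for the solid component (values are capped
    one decimal below the drawn total diameter to keep records valid).
    """

    count: int
    density_type: DensityType
    pathology: str
    size_range: Tuple[float, float]
    solid_range: Optional[Tuple[float, float]] = None
    malignant_signs: frozenset = frozenset()
    benign_features: frozenset = frozenset()
    endobronchial: bool = False
    stability_months: Optional[float] = None
    course: str = "unknown"
    pathology_subtype: Optional[str] = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("block count must be non-negative")
        if isinstance(self.density_type, str) and not isinstance(self.density_type, DensityType):
            object.__setattr__(self, "density_type", DensityType(self.density_type))
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology: {self.pathology!r}")
        if self.course not in COURSES:
            raise ValueError(f"unknown course: {self.course!r}")
        unknown = frozenset(self.malignant_signs) - MALIGNANT_SIGNS
        if unknown:
            raise ValueError(f"unknown sign token(s): {sorted(unknown)}")
        unknown = frozenset(self.benign_features) - BENIGN_FEATURES
        if unknown:
            raise ValueError(f"unknown feature token(s): {sorted(unknown)}")
        object.__setattr__(self, "malignant_signs", frozenset(self.malignant_signs))
        object.__setattr__(self, "benign_features", frozenset(self.benign_features))
        for name in ("size_range", "solid_range"):
            rng = getattr(self, name)
            if rng is None:
                continue
            if isinstance(rng, (int, float)):
                rng = (float(rng), float(rng))
            else:
                rng = (float(rng[0]), float(rng[1]))
            if rng[0] > rng[1]:
                raise ValueError(f"{name} low > high: {rng}")
            object.__setattr__(self, name, rng)
        if self.density_type is DensityType.PSN and self.solid_range is None:
            raise ValueError("PSN blocks require a solid_range")
        if self.density_type is not DensityType.PSN and self.solid_range is not None:
            raise ValueError("solid_range is only meaningful for PSN blocks")


_SPEC_KEYS = {"blocks", "seed"}
_BLOCK_KEYS = {
    "count",
    "density_type",
    "pathology",
    "size_range",
    "solid_range",
    "malignant_signs",
    "benign_features",
    "endobronchial",
    "stability_months",
    "course",
    "pathology_subtype",
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition recipe: an ordered list of blocks plus a seed."""

    blocks: Tuple[CohortBlock, ...]
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        unknown = set(data) - _SPEC_KEYS
        if unknown:
            raise ValueError(f"unknown cohort-spec key(s): {sorted(unknown)}")
        blocks = []
        for i, raw in enumerate(data.get("blocks", [])):
            bad = set(raw) - _BLOCK_KEYS
            if bad:
                raise ValueError(f"block {i}: unknown key(s) {sorted(bad)}")
            kw = dict(raw)
            for key in ("malignant_signs", "benign_features"):
                if key in kw and kw[key] is not None:
                    kw[key] = frozenset(kw[key])
            for key in ("size_range", "solid_range"):
                if key in kw and kw[key] is not None and not isinstance(kw[key], (int, float)):
                    kw[key] = tuple(kw[key])
            blocks.append(CohortBlock(**kw))
        return cls(blocks=tuple(blocks), seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _draw_mm(rng: np.random.Generator, low: float, high: float) -> float:
    """Uniform draw on [low, high], rounded to the one-decimal grid."""
    if low == high:
        return round(low, 1)
    return round(float(rng.uniform(low, high)), 1)


def generate_cohort(spec: CohortSpec) -> List[NoduleRecord]:
    """Materialize a recipe into validated records (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    records: List[NoduleRecord] = []
    for bi, block in enumerate(spec.blocks):
        for i in range(block.count):
            d = _draw_mm(rng, *block.size_range)
            d = min(max(d, 0.1), 30.0)
            solid = None
            if block.solid_range is not None:
                solid = _draw_mm(rng, *block.solid_range)
                solid = min(solid, round(d - 0.1, 1))
                solid = max(solid, 0.1)
            rec = NoduleRecord(
                id=f"{block.density_type.value}-{block.pathology}-b{bi}-{i:05d}",
                density_type=block.density_type,
                mean_diameter=d,
                solid_component_diameter=solid,
                malignant_signs=block.malignant_signs,
                benign_features=block.benign_features,
                endobronchial=block.endobronchial,
                stability_months=block.stability_months,
                course=block.course,
                pathology=block.pathology,
                pathology_subtype=block.pathology_subtype,
            )
            records.append(validate_record(rec))
    return records


# --- deterministic reconstruction -----------------------------------------
#
# Each plan row is (count, density, pathology, mean mm, solid mm, signs,
# features): one concrete feasible joint per stratum, maximum concordance.
# Template behaviour (PNI screen, Lung-RADS screen):
#   SN  10.0                      -> (IIIa +, 4A +)
#   SN   5.5 + vacuole            -> (IIIa +, 2  -)
#   SN   4.0                      -> (I    -, 2  -)
#   SN   9.0 + satellite lesions  -> (II   -, 4A +)
#   PSN 10.0/6.0                  -> (IV   +, 4A +)
#   PSN  5.5/2.0 + vacuole        -> (IIIa +, 2  -)
#   PSN  4.0/2.0                  -> (I    -, 2  -)
#   PSN  9.0/4.0 + satellite      -> (II   -, 3  +)
#   GGN 10.0                      -> (IIIa +, 2  -)
#   GGN  4.0                      -> (I    -, 2  -)
RECONSTRUCTION_PLAN: Tuple[Tuple[int, str, str, float, Optional[float], tuple, tuple], ...] = (
    # SN, malignant 1851: Lung TP 1839 / FN 12; PNI TP 1848 / FN 3
    (1839, "SN", "malignant", 10.0, None, (), ()),
    (9, "SN", "malignant", 5.5, None, ("vacuole",), ()),
    (3, "SN", "malignant", 4.0, None, (), ()),
    # SN, benign 1167: Lung FP 757 / TN 410; PNI FP 569 / TN 598
    (569, "SN", "benign", 10.0, None, (), ()),
    (188, "SN", "benign", 9.0, None, (), ("satellite_lesions",)),
    (410, "SN", "benign", 4.0, None, (), ()),
    # PSN, malignant 1604: Lung TP 1578 / FN 26; PNI TP 1602 / FN 2
    (1578, "PSN", "malignant", 10.0, 6.0, (), ()),
    (24, "PSN", "malignant", 5.5, 2.0, ("vacuole",), ()),
    (2, "PSN", "malignant", 4.0, 2.0, (), ()),
    # PSN, benign 105: Lung FP 99 / TN 6; PNI FP 91 / TN 14
    (91, "PSN", "benign", 10.0, 6.0, (), ()),
    (8, "PSN", "benign", 9.0, 4.0, (), ("satellite_lesions",)),
    (6, "PSN", "benign", 4.0, 2.0, (), ()),
    # GGN, malignant 2488: Lung TP 0 / FN 2488; PNI TP 2401 / FN 87
    (2401, "GGN", "malignant", 10.0, None, (), ()),
    (87, "GGN", "malignant", 4.0, None, (), ()),
    # GGN, benign 566: Lung FP 0 / TN 566; PNI FP 262 / TN 304
    (262, "GGN", "benign", 10.0, None, (), ()),
    (304, "GGN", "benign", 4.0, None, (), ()),
)

#: Malignant-GGN pathology subtype counts: AIS / MIA / IAC plus a 3-record
#: remainder whose subtype is not published, labelled "other".
GGN_SUBTYPE_COUNTS: Tuple[Tuple[str, int], ...] = (
    ("AIS", 979),
    ("MIA", 946),
    ("IAC", 560),
    ("other", 3),
)


def reconstruct_evaluation_cohort(tag_subtypes: bool = False) -> List[NoduleRecord]:
    """Deterministically rebuild the 7,781-nodule evaluation cohort.

    Classifying the result with both engines and tabulating per stratum
    reproduces every published screening cell count exactly; the totals are
    the sums of the per-type rows by construction.
    """
    records: List[NoduleRecord] = []
    for bi, (count, density, pathology, d, solid, signs, features) in enumerate(
        RECONSTRUCTION_PLAN
    ):
        for i in range(count):
            rec = NoduleRecord(
                id=f"EC-{density}-{pathology[:3]}-b{bi:02d}-{i:05d}",
                density_type=DensityType(density),
                mean_diameter=d,
                solid_component_diameter=solid,
                malignant_signs=frozenset(signs),
                benign_features=frozenset(features),
                pathology=pathology,
            )
            records.append(validate_record(rec))
    if tag_subtypes:
        records = tag_pathology_subtypes(records)
    return records


def tag_pathology_subtypes(cohort: Sequence[NoduleRecord]) -> List[NoduleRecord]:
    """Label malignant GGNs with AIS / MIA / IAC subtypes in cohort order.

    The subtype split applies to the 2,488 malignant GGNs of the
    reconstructed cohort; labels never affect classification. Raises if the
    malignant-GGN count does not match the published total.
    """
    expected = sum(n for _, n in GGN_SUBTYPE_COUNTS)
    targets = [
        i
        for i, r in enumerate(cohort)
        if r.density_type is DensityType.GGN and r.pathology == "malignant"
    ]
    if len(targets) != expected:
        raise ValueError(
            f"subtype tagging expects {expected} malignant GGNs, found {len(targets)}"
        )
    labels: List[str] = []
    for label, n in GGN_SUBTYPE_COUNTS:
        labels.extend([label] * n)
    out = list(cohort)
    for idx, label in zip(targets, labels):
        out[idx] = out[idx].with_(pathology_subtype=label)
    return out


def reconstruction_metadata() -> Dict[str, dict]:
    """Per-stratum joint cross-classification fixed by the reconstruction."""
    meta: Dict[str, dict] = {}
    for count, density, pathology, d, solid, signs, features in RECONSTRUCTION_PLAN:
        key = f"{density}/{pathology}/d={d}" + (f"/s={solid}" if solid else "")
        meta[key] = {
            "count": count,
            "malignant_signs": sorted(signs),
            "benign_features": sorted(features),
        }
    return meta
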