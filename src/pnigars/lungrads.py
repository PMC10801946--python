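"""Lung-RADS 2022 category assignment as exercised in nodule screening.

Baseline rules (ACR Lung-RADS v2022, size-based pathway):

* completely calcified nodules and fat-containing nodules (hamartoma
  pattern) are category 1; perifissural benign-appearing nodules category 2;
* ground-glass (nonsolid) nodules under 30 mm are category 2 irrespective of
  size or signs;
* solid nodules: < 6 mm → 2, 6 to < 8 mm → 3, 8 to < 15 mm → 4A,
  ≥ 15 mm → 4B;
* part-solid nodules: total diameter < 6 mm → 2; otherwise the solid
  component decides — < 6 mm → 3, 6 to < 8 mm → 4A, ≥ 8 mm → 4B;
* a category-3/4 nodule with additional suspicious findings becomes 4X.

Stability downgrade: a category-3 nodule unchanged for ≥ 6 months becomes 2;
a 4A nodule unchanged for ≥ 3 months becomes 3 (and, if the documented
stable interval also covers the further 6 months, 2). Categories 1, 2, 4B
and 4X are not downgraded by stability.

Categories 1-2 dichotomize to a negative screen, 3/4A/4B/4X to positive.
"""

from __future__ import annotations

from typing import Optional

from .records import DensityType, LungRadsCategory, NoduleRecord, ScreenLabel

__all__ = [
    "baseline_category",
    "apply_stability_downgrade",
    "classify_lungrads",
    "dichotomize_lungrads",
    "DEFAULT_4X_TRIGGERS",
    "CATEGORY_1_FEATURES",
]

#: Benign morphologies mapping straight to category 1.
CATEGORY_1_FEATURES = frozenset({"pure_calcification", "fat"})

#: Additional findings that promote a category-3/4 nodule to 4X.
DEFAULT_4X_TRIGGERS = frozenset({"spiculation", "enlarged_lymph_nodes", "ggn_doubling_1yr"})

_POSITIVE = frozenset(
    {LungRadsCategory.C3, LungRadsCategory.C4A, LungRadsCategory.C4B, LungRadsCategory.C4X}
)


def _solid_size_category(d: float) -> LungRadsCategory:
    if d < 6.0:
        return LungRadsCategory.C2
    if d < 8.0:
        return LungRadsCategory.C3
    if d < 15.0:
        return LungRadsCategory.C4A
    return LungRadsCategory.C4B


def _part_solid_category(total: float, solid: float) -> LungRadsCategory:
    if total < 6.0:
        return LungRadsCategory.C2
    if solid < 6.0:
        return LungRadsCategory.C3
    if solid < 8.0:
        return LungRadsCategory.C4A
    return LungRadsCategory.C4B


def baseline_category(
    record: NoduleRecord, fourx_triggers: frozenset = DEFAULT_4X_TRIGGERS
) -> LungRadsCategory:
    """Baseline (pre-follow-up) Lung-RADS category of a validated record."""
    features = record.benign_features
    if features & CATEGORY_1_FEATURES:
        return LungRadsCategory.C1
    if record.density_type is DensityType.GGN:
        # All nonsolid nodules in the valid domain (<= 30 mm) are category 2.
        return LungRadsCategory.C2
    if "perifissural" in features:
        return LungRadsCategory.C2

    if record.density_type is DensityType.SN:
        category = _solid_size_category(record.mean_diameter)
    else:
        category = _part_solid_category(
            record.mean_diameter, record.solid_component_diameter or 0.0
        )

    if category in _POSITIVE and record.malignant_signs & fourx_triggers:
        return LungRadsCategory.C4X
    return category


def apply_stability_downgrade(
    category: LungRadsCategory, stability_months: Optional[float]
) -> LungRadsCategory:
    """Downgrade 4A/3 for documented stability; other categories pass through.

    The stable interval is spent sequentially: 4A needs 3 months to reach 3
    and a further 6 to reach 2; 3 needs 6 months to reach 2.
    """
    if stability_months is None:
        return category
    remaining = stability_months
    if category is LungRadsCategory.C4A and remaining >= 3.0:
        category = LungRadsCategory.C3
        remaining -= 3.0
    if category is LungRadsCategory.C3 and remaining >= 6.0:
        category = LungRadsCategory.C2
    return category


def classify_lungrads(
    record: NoduleRecord, fourx_triggers: frozenset = DEFAULT_4X_TRIGGERS
) -> LungRadsCategory:
    """Baseline category plus the stability downgrade.

    Stability is consulted only when the course is not ``increased``; growth
    handling beyond that is out of scope for a single-baseline cohort.
    """
    category = baseline_category(record, fourx_triggers)
    if record.course != "increased":
        category = apply_stability_downgrade(category, record.stability_months)
    return category


def dichotomize_lungrads(category: LungRadsCategory) -> ScreenLabel:
    """Negative screen for categories 1-2, positive for 3 and any 4."""
    return ScreenLabel.POSITIVE if category in _POSITIVE else ScreenLabel.NEGATIVE
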