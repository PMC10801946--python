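"""PNI-GARS grading engine.

The Pulmonary Node Imaging-Grading And Reporting System assigns an ordered
grade 0 / I / II / IIIa / IIIb / IIIc / IV from nodule size, density,
imaging signs, benign features and follow-up stability:

* definitely-benign morphologies (pure calcification, fat, spherical
  atelectasis, perifissural nodule) are grade 0;
* micronodules (≤ 5 mm, any density) are grade I, as are nodules proven
  stable long enough for their density class (solid ≥ 2 years, sub-solid
  ≥ 5 years) or that shrank or disappeared on follow-up;
* size tiers otherwise set the base grade — 5–8 mm → II, 8–10 mm → IIIa,
  10–20 mm → IIIb, 20–30 mm → IIIc (intervals half-open: lower bound
  exclusive, upper inclusive);
* a partial-solid nodule whose solid component exceeds 5 mm is grade IV
  outright; an endobronchial nodule is floored at grade III;
* one sign of early malignancy lifts the grade one sub-level; two or more
  signs, or spiculation by itself, force grade IV;
* satellite lesions (or a combined clinical + CT picture of inflammation)
  lower the grade one level, never below I.

Grades 0/I/II dichotomize to a negative screen, III/IV to positive.

Rule precedence is: definitely-benign > stability/course > base grade >
sign upgrades > benign downgrade > endobronchial floor, so a calcified or
long-stable nodule can never be upgraded by signs, and an endobronchial
nodule can never be argued below grade III.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .records import DensityType, NoduleRecord, PniGrade, ScreenLabel

__all__ = [
    "GradingTrace",
    "base_grade",
    "apply_malignant_signs",
    "apply_benign_adjustment",
    "apply_stability",
    "classify_pnigars",
    "dichotomize_pni",
    "SPECIAL_SIGNS",
    "FORCE_IV_SIGNS",
    "BENIGN_DEFINITE",
]

#: Special signs of early malignant lesions (upgrade ladder drivers).
SPECIAL_SIGNS = frozenset({"vacuole", "vascular_convergence", "solid_component_in_ggn"})

#: Signs that force grade IV on their own.
FORCE_IV_SIGNS = frozenset({"spiculation"})

#: Definitely-benign morphologies: grade 0, no further rules considered.
BENIGN_DEFINITE = frozenset(
    {"pure_calcification", "fat", "spherical_atelectasis", "perifissural"}
)

# One-sub-level upgrade ladder.
_LADDER = [PniGrade.II, PniGrade.IIIA, PniGrade.IIIB, PniGrade.IIIC, PniGrade.IV]

# Full downgrade chain (grade 0 is reserved for definitely-benign morphology,
# so the benign-feature downgrade floors at I).
_DOWN_CHAIN = [PniGrade.I, PniGrade.II, PniGrade.IIIA, PniGrade.IIIB, PniGrade.IIIC, PniGrade.IV]

#: Stability thresholds, months, by density class (2 years solid, 5 years sub-solid).
STABILITY_MONTHS_SOLID = 24.0
STABILITY_MONTHS_SUBSOLID = 60.0


@dataclass(frozen=True)
class GradingTrace:
    """Audit trail of one grading run.

    ``applied_rules`` is an ordered tuple of ``(rule_id, grade_after)``
    pairs; replaying them from ``base_grade`` reproduces ``final_grade``.
    """

    base_grade: PniGrade
    applied_rules: Tuple[Tuple[str, PniGrade], ...]
    final_grade: PniGrade

    def replay(self) -> PniGrade:
        grade = self.base_grade
        for _rule, after in self.applied_rules:
            grade = after
        return grade

    def rule_ids(self) -> Tuple[str, ...]:
        return tuple(rule for rule, _ in self.applied_rules)


def _size_tier(diameter: float) -> PniGrade:
    """Base grade from mean diameter alone (half-open tiers, upper inclusive)."""
    if diameter <= 5.0:
        return PniGrade.I
    if diameter <= 8.0:
        return PniGrade.II
    if diameter <= 10.0:
        return PniGrade.IIIA
    if diameter <= 20.0:
        return PniGrade.IIIB
    return PniGrade.IIIC


def _endobronchial_floor(diameter: float) -> PniGrade:
    # Grade III without a stated sub-tier: realized as IIIb for 10-20 mm,
    # otherwise the size tier but at least IIIa.
    if 10.0 < diameter <= 20.0:
        return PniGrade.IIIB
    return max(_size_tier(diameter), PniGrade.IIIA)


def base_grade(record: NoduleRecord) -> PniGrade:
    """Grade from size and density alone (no signs, no benign features).

    A PSN whose solid component exceeds 5 mm is grade IV regardless of the
    size tier; an endobronchial nodule is floored at grade III.
    """
    tier = _size_tier(record.mean_diameter)
    if (
        record.density_type is DensityType.PSN
        and record.solid_component_diameter is not None
        and record.solid_component_diameter > 5.0
    ):
        return PniGrade.IV
    if record.endobronchial:
        return max(tier, _endobronchial_floor(record.mean_diameter))
    return tier


def apply_malignant_signs(grade: PniGrade, signs: frozenset) -> PniGrade:
    """Upgrade a grade for signs of early malignancy.

    One qualifying sign lifts one sub-level (II→IIIa→IIIb→IIIc→IV); two or
    more, or spiculation alone, force IV. Micronodules and benign grades
    (< II) are never upgraded by signs.
    """
    if grade < PniGrade.II:
        return grade
    qualifying = frozenset(signs)
    if qualifying & FORCE_IV_SIGNS or len(qualifying) >= 2:
        return PniGrade.IV
    if len(qualifying) == 1:
        idx = _LADDER.index(grade)
        return _LADDER[min(idx + 1, len(_LADDER) - 1)]
    return grade


def apply_benign_adjustment(grade: PniGrade, features: frozenset) -> PniGrade:
    """Downgrade one level for satellite lesions or a full inflammation picture.

    The floor is grade I: grade 0 is reserved for the enumerated
    definitely-benign morphologies.
    """
    features = frozenset(features)
    inflammatory = {"inflammation_clinical", "inflammation_ct"} <= features
    if "satellite_lesions" in features or inflammatory:
        if grade in _DOWN_CHAIN:
            idx = _DOWN_CHAIN.index(grade)
            return _DOWN_CHAIN[max(idx - 1, 0)]
    return grade


def _stability_rule(record: NoduleRecord) -> Optional[str]:
    """Rule id of the stability/course rule that applies, or None."""
    if record.course in ("decreased", "disappeared"):
        return f"course_{record.course}"
    if record.course == "increased":
        return None
    if record.stability_months is None:
        return None
    threshold = (
        STABILITY_MONTHS_SOLID
        if record.density_type is DensityType.SN
        else STABILITY_MONTHS_SUBSOLID
    )
    if record.stability_months >= threshold:
        return f"stable_{int(threshold)}m"
    return None


def apply_stability(record: NoduleRecord, grade: PniGrade) -> PniGrade:
    """Downgrade to grade I for documented long-term stability or regression.

    Solid nodules need ≥ 24 unchanged months, sub-solid ≥ 60; a decreased or
    disappeared course downgrades regardless of the interval. Grade 0 is
    left alone (it is already definitely benign).
    """
    if grade is PniGrade.G0:
        return grade
    if _stability_rule(record) is not None:
        return PniGrade.I
    return grade


def classify_pnigars(record: NoduleRecord) -> Tuple[PniGrade, GradingTrace]:
    """Full PNI-GARS classification with an audit trace."""
    if record.benign_features & BENIGN_DEFINITE:
        trace = GradingTrace(PniGrade.G0, (("benign_definite", PniGrade.G0),), PniGrade.G0)
        return PniGrade.G0, trace

    stability_rule = _stability_rule(record)
    if stability_rule is not None:
        trace = GradingTrace(PniGrade.I, ((stability_rule, PniGrade.I),), PniGrade.I)
        return PniGrade.I, trace

    base = base_grade(record)
    applied = []
    grade = base

    upgraded = apply_malignant_signs(grade, record.malignant_signs)
    if upgraded is not grade:
        nsigns = len(record.malignant_signs)
        rule = (
            "signs_force_iv"
            if (record.malignant_signs & FORCE_IV_SIGNS or nsigns >= 2)
            else "signs_one_sublevel"
        )
        applied.append((rule, upgraded))
        grade = upgraded

    adjusted = apply_benign_adjustment(grade, record.benign_features)
    if adjusted is not grade:
        applied.append(("benign_downgrade", adjusted))
        grade = adjusted

    if record.endobronchial:
        floor = _endobronchial_floor(record.mean_diameter)
        if grade < floor:
            applied.append(("endobronchial_floor", floor))
            grade = floor

    trace = GradingTrace(base, tuple(applied), grade)
    return grade, trace


def dichotomize_pni(grade: PniGrade) -> ScreenLabel:
    """Negative screen for grades 0/I/II, positive for III (any sub-tier) and IV."""
    return ScreenLabel.POSITIVE if grade >= PniGrade.IIIA else ScreenLabel.NEGATIVE
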