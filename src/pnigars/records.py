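"""Core domain types for pulmonary-nodule classification.

A screening-detected pulmonary nodule is described by its density class
(solid SN, partial-solid PSN, ground-glass GGN), its mean diameter on the
lung window (average of long and short axes, reported to one decimal
millimetre), the diameter of any solid component (PSNs only), margin
morphology, imaging signs associated with early malignancy, definitely- or
probably-benign features, follow-up stability, and — for cohorts with a
surgical reference standard — the pathological truth.

Both rule engines (:mod:`pnigars.grading`, :mod:`pnigars.lungrads`) consume
the same :class:`NoduleRecord`; validation guarantees that every record that
enters an engine classifies without error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from functools import total_ordering
from typing import Iterable, Optional

__all__ = [
    "DensityType",
    "PniGrade",
    "LungRadsCategory",
    "ScreenLabel",
    "NoduleRecord",
    "RecordValidationError",
    "validate_record",
    "MALIGNANT_SIGNS",
    "BENIGN_FEATURES",
    "MARGINS",
    "COURSES",
    "PATHOLOGIES",
]


class DensityType(str, enum.Enum):
    """Nodule density class on thin-slice CT."""

    SN = "SN"      #: solid — denser than vessels, visible in the mediastinal window
    PSN = "PSN"    #: partial solid — a solid core within ground-glass opacity
    GGN = "GGN"    #: ground-glass (nonsolid) — does not obscure passing vessels


@total_ordering
class _OrderedEnum(enum.Enum):
    """Enum whose members are totally ordered by definition order."""

    def __lt__(self, other):
        if self.__class__ is other.__class__:
            members = list(self.__class__)
            return members.index(self) < members.index(other)
        return NotImplemented


class PniGrade(_OrderedEnum):
    """PNI-GARS grade: 0 (definitely benign) through IV (highly suspicious).

    Grade III is subdivided by size into IIIa (8–10 mm), IIIb (10–20 mm) and
    IIIc (20–30 mm). Grade V (pathology-confirmed malignancy) is not an
    imaging decision and is deliberately absent.
    """

    G0 = "0"
    I = "I"
    II = "II"
    IIIA = "IIIa"
    IIIB = "IIIb"
    IIIC = "IIIc"
    IV = "IV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "PniGrade":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown PNI-GARS grade label: {label!r}")


class LungRadsCategory(_OrderedEnum):
    """Lung-RADS category 1 through 4X.

    4X flags a category-3/4 nodule with additional suspicious imaging
    findings; for dichotomization it ranks above 4B (most suspicious).
    """

    C1 = "1"
    C2 = "2"
    C3 = "3"
    C4A = "4A"
    C4B = "4B"
    C4X = "4X"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "LungRadsCategory":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown Lung-RADS category label: {label!r}")


class ScreenLabel(str, enum.Enum):
    """Dichotomized screening result."""

    NEGATIVE = "negative"
    POSITIVE = "positive"


# Vocabulary of imaging signs associated with early malignant lesions.
# The "special" subset (vacuole, vascular convergence, solid component of a
# GGN) drives the one-sign/two-sign upgrade ladder; spiculation forces the
# top grade; the remainder are suspicious signs counted in the same ladder.
MALIGNANT_SIGNS = frozenset(
    {
        "vacuole",
        "vascular_convergence",
        "solid_component_in_ggn",
        "spiculation",
        "pleural_indentation",
        "lobulation_sign",
        "ggn_doubling_1yr",
        "ggn_density_above_minus600",
        "enlarged_lymph_nodes",
        "shrunk_but_denser",
    }
)

# Benign-indicating features: the first four are definitely-benign
# morphologies (grade 0 / category 1-2); satellite lesions and a combined
# clinical+CT inflammation picture trigger a one-level downgrade.
BENIGN_FEATURES = frozenset(
    {
        "pure_calcification",
        "fat",
        "spherical_atelectasis",
        "perifissural",
        "satellite_lesions",
        "inflammation_clinical",
        "inflammation_ct",
    }
)

MARGINS = frozenset({"smooth", "partial_smooth", "lobulation", "short_spinous", "vague"})
COURSES = frozenset({"unchanged", "decreased", "disappeared", "increased", "unknown"})
PATHOLOGIES = frozenset({"benign", "malignant"})

#: Cohorts exclude nodules larger than 30 mm.
MAX_DIAMETER_MM = 30.0


class RecordValidationError(ValueError):
    """A nodule record violates an invariant of the valid domain.

    ``code`` is a stable machine-readable reason; ``record_id`` names the
    offending record when known.
    """

    def __init__(self, code: str, message: str, record_id: Optional[str] = None):
        self.code = code
        self.record_id = record_id
        prefix = f"record {record_id!r}: " if record_id else ""
        super().__init__(f"{prefix}{message} [{code}]")


@dataclass(frozen=True)
class NoduleRecord:
    """One pulmonary nodule: imaging features, follow-up, and truth.

    Parameters
    ----------
    id : str
        Opaque identifier.
    density_type : DensityType
        SN, PSN or GGN.
    mean_diameter : float
        Mean of long and short axes, millimetres (one decimal by convention).
    solid_component_diameter : float, optional
        Diameter of the solid core, millimetres. Present iff PSN.
    margin : str, optional
        Margin descriptor (``smooth`` … ``vague``); descriptive only.
    malignant_signs : frozenset of str
        Imaging signs of early malignancy (see :data:`MALIGNANT_SIGNS`).
    benign_features : frozenset of str
        Benign-indicating features (see :data:`BENIGN_FEATURES`).
    endobronchial : bool
        Endobronchial location (PNI-GARS grade-III floor).
    stability_months : float, optional
        Longest documented interval over which the nodule was unchanged.
    course : str
        Follow-up course: unchanged / decreased / disappeared / increased /
        unknown.
    pathology : str, optional
        Reference-standard truth (``benign`` / ``malignant``) when available.
    pathology_subtype : str, optional
        Free label (AIS, MIA, IAC, hamartoma, …); never consulted by the
        engines.
    """

    id: str
    density_type: DensityType
    mean_diameter: float
    solid_component_diameter: Optional[float] = None
    margin: Optional[str] = None
    malignant_signs: frozenset = frozenset()
    benign_features: frozenset = frozenset()
    endobronchial: bool = False
    stability_months: Optional[float] = None
    course: str = "unknown"
    pathology: Optional[str] = None
    pathology_subtype: Optional[str] = None

    def __post_init__(self):
        if isinstance(self.density_type, str) and not isinstance(self.density_type, DensityType):
            object.__setattr__(self, "density_type", DensityType(self.density_type))
        if not isinstance(self.malignant_signs, frozenset):
            object.__setattr__(self, "malignant_signs", frozenset(self.malignant_signs))
        if not isinstance(self.benign_features, frozenset):
            object.__setattr__(self, "benign_features", frozenset(self.benign_features))

    def with_(self, **changes) -> "NoduleRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def validate_record(record: NoduleRecord) -> NoduleRecord:
    """Check every domain invariant; return the record unchanged if valid.

    Raises
    ------
    RecordValidationError
        With a reason code: ``diameter_out_of_range``,
        ``missing_solid_component``, ``unexpected_solid_component``,
        ``solid_component_size``, ``unknown_malignant_sign``,
        ``unknown_benign_feature``, ``unknown_margin``, ``unknown_course``,
        ``unknown_pathology`` or ``negative_stability``.
    """
    rid = record.id

    d = record.mean_diameter
    if not (0.0 < d <= MAX_DIAMETER_MM):
        raise RecordValidationError(
            "diameter_out_of_range",
            f"mean diameter must satisfy 0 < d <= {MAX_DIAMETER_MM:g} mm, got {d!r}",
            rid,
        )

    solid = record.solid_component_diameter
    if record.density_type is DensityType.PSN:
        if solid is None:
            raise RecordValidationError(
                "missing_solid_component",
                "a partial-solid nodule requires a solid-component diameter",
                rid,
            )
        if not (0.0 < solid < d):
            raise RecordValidationError(
                "solid_component_size",
                f"solid component must satisfy 0 < s < mean diameter, got {solid!r}",
                rid,
            )
    elif solid is not None:
        raise RecordValidationError(
            "unexpected_solid_component",
            f"{record.density_type.value} nodules carry no solid-component diameter",
            rid,
        )

    unknown = record.malignant_signs - MALIGNANT_SIGNS
    if unknown:
        raise RecordValidationError(
            "unknown_malignant_sign", f"unknown sign token(s): {sorted(unknown)}", rid
        )
    unknown = record.benign_features - BENIGN_FEATURES
    if unknown:
        raise RecordValidationError(
            "unknown_benign_feature", f"unknown feature token(s): {sorted(unknown)}", rid
        )

    if record.margin is not None and record.margin not in MARGINS:
        raise RecordValidationError("unknown_margin", f"unknown margin: {record.margin!r}", rid)
    if record.course not in COURSES:
        raise RecordValidationError("unknown_course", f"unknown course: {record.course!r}", rid)
    if record.pathology is not None and record.pathology not in PATHOLOGIES:
        raise RecordValidationError(
            "unknown_pathology", f"unknown pathology: {record.pathology!r}", rid
        )
    if record.stability_months is not None and record.stability_months < 0:
        raise RecordValidationError(
            "negative_stability",
            f"stability must be non-negative, got {record.stability_months!r}",
            rid,
        )
    return record
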