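"""Cohort readers and writers.

Fixed CSV dialect for reproducibility: comma-delimited, UTF-8, header
mandatory, "." decimal, list-valued fields semicolon-joined, booleans
``true``/``false``. Diameters are written with one decimal. A write/read
round trip preserves every field value exactly.
"""

from __future__ import annotations

import csv
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .records import DensityType, NoduleRecord, RecordValidationError, validate_record

__all__ = ["COLUMNS", "CohortFormatError", "read_cohort", "write_cohort", "records_to_frame"]

COLUMNS = [
    "id",
    "density_type",
    "mean_diameter",
    "solid_component_diameter",
    "margin",
    "malignant_signs",
    "benign_features",
    "endobronchial",
    "stability_months",
    "course",
    "pathology",
    "pathology_subtype",
]


class CohortFormatError(ValueError):
    """A cohort file is malformed; ``errors`` lists (line_number, message)."""

    def __init__(self, path, errors: Sequence):
        self.path = path
        self.errors = list(errors)
        shown = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{path}: {shown}{more}")


def _parse_float(token: str) -> Optional[float]:
    token = token.strip()
    return float(token) if token else None


def _parse_set(token: str) -> frozenset:
    token = token.strip()
    if not token:
        return frozenset()
    return frozenset(t.strip() for t in token.split(";") if t.strip())


def _parse_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no", ""):
        return False
    raise ValueError(f"not a boolean: {token!r}")


def _row_to_record(row: dict) -> NoduleRecord:
    return NoduleRecord(
        id=row["id"].strip(),
        density_type=DensityType(row["density_type"].strip()),
        mean_diameter=float(row["mean_diameter"]),
        solid_component_diameter=_parse_float(row.get("solid_component_diameter", "")),
        margin=(row.get("margin", "").strip() or None),
        malignant_signs=_parse_set(row.get("malignant_signs", "")),
        benign_features=_parse_set(row.get("benign_features", "")),
        endobronchial=_parse_bool(row.get("endobronchial", "")),
        stability_months=_parse_float(row.get("stability_months", "")),
        course=(row.get("course", "").strip() or "unknown"),
        pathology=(row.get("pathology", "").strip() or None),
        pathology_subtype=(row.get("pathology_subtype", "").strip() or None),
    )


def read_cohort(path) -> List[NoduleRecord]:
    """Read and validate a cohort CSV; reports every bad row with its line number."""
    records: List[NoduleRecord] = []
    errors: List = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(path, [(1, "empty file")])
        missing = {"id", "density_type", "mean_diameter"} - set(reader.fieldnames)
        if missing:
            raise CohortFormatError(path, [(1, f"missing required column(s): {sorted(missing)}")])
        for line_no, row in enumerate(reader, start=2):
            try:
                records.append(validate_record(_row_to_record(row)))
            except (RecordValidationError, ValueError, KeyError) as exc:
                errors.append((line_no, str(exc)))
    if errors:
        raise CohortFormatError(path, errors)
    return records


def _fmt_float(value: Optional[float]) -> str:
    return "" if value is None else f"{value:g}"


def write_cohort(records: Iterable[NoduleRecord], path) -> None:
    """Write records to CSV (deterministic byte-level output for equal input)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.density_type.value,
                    f"{r.mean_diameter:.1f}",
                    "" if r.solid_component_diameter is None else f"{r.solid_component_diameter:.1f}",
                    r.margin or "",
                    ";".join(sorted(r.malignant_signs)),
                    ";".join(sorted(r.benign_features)),
                    "true" if r.endobronchial else "false",
                    _fmt_float(r.stability_months),
                    r.course,
                    r.pathology or "",
                    r.pathology_subtype or "",
                ]
            )


def records_to_frame(records: Sequence[NoduleRecord]) -> pd.DataFrame:
    """Field-per-column DataFrame view of a cohort (sets semicolon-joined)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "density_type": [r.density_type.value for r in records],
            "mean_diameter": [r.mean_diameter for r in records],
            "solid_component_diameter": [r.solid_component_diameter for r in records],
            "margin": [r.margin for r in records],
            "malignant_signs": [";".join(sorted(r.malignant_signs)) for r in records],
            "benign_features": [";".join(sorted(r.benign_features)) for r in records],
            "endobronchial": [r.endobronchial for r in records],
            "stability_months": [r.stability_months for r in records],
            "course": [r.course for r in records],
            "pathology": [r.pathology for r in records],
            "pathology_subtype": [r.pathology_subtype for r in records],
        }
    )
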