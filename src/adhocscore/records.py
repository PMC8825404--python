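"""Trauma-bay patient records: data model, CSV I/O, validation, cohort filters.

A :class:`PatientRecord` carries the demographics, trauma-bay vitals,
point-of-care labs, head-injury findings and outcomes needed to compute
trauma-bay risk scores.  Every clinical field is individually optional
(``None`` means *not observed*), because real registry exports are never
complete and the scores downstream have explicit missing-data semantics.

CSV/TSV serialization uses one canonical column per field; AIS injury items
are packed into a single cell as semicolon-separated ``region:severity``
pairs.  Unknown columns survive a round trip in :attr:`PatientRecord.extras`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Optional

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "other")
MECHANISMS = ("blunt", "penetrating")
ECS_MOTOR = ("normal", "non_specific", "none")
ECS_BINARY = ("normal", "not_normal")

#: the six ISS body regions of the Abbreviated Injury Scale
BODY_REGIONS = (
    "head_neck",
    "face",
    "chest",
    "abdomen",
    "extremities_pelvis",
    "external",
)


@dataclass(frozen=True)
class AisItem:
    """One injury coded on the Abbreviated Injury Scale (severity 1-6)."""

    body_region: str
    severity: int

    def __post_init__(self) -> None:
        if self.body_region not in BODY_REGIONS:
            raise ValueError(f"unknown AIS body region {self.body_region!r}")
        if not (isinstance(self.severity, int) and 1 <= self.severity <= 6):
            raise ValueError(f"AIS severity must be an integer in 1..6, got {self.severity!r}")


@dataclass
class PatientRecord:
    """One trauma-bay patient.  All clinical fields optional (None = absent)."""

    id: str = ""
    age: Optional[int] = None                 # years
    sex: Optional[str] = None
    mechanism: Optional[str] = None
    gcs: Optional[int] = None                 # Glasgow Coma Scale, 3..15
    ecs_motor: Optional[str] = None
    ecs_pupil_size: Optional[str] = None
    ecs_pupil_reactivity: Optional[str] = None
    base_excess: Optional[float] = None       # mmol/L
    intubated: Optional[bool] = None
    pao2_fio2: Optional[float] = None         # Horowitz ratio, meaningful when intubated
    hemothorax: Optional[bool] = None
    sbp: Optional[float] = None               # admission systolic BP, mmHg
    hb: Optional[float] = None                # hemoglobin, configured unit (default g/dL)
    inr: Optional[float] = None
    prbc_transfused: Optional[bool] = None
    fracture_pelvis: Optional[bool] = None
    fracture_femur: Optional[bool] = None
    fracture_tibia: Optional[bool] = None
    ais_items: Optional[list[AisItem]] = None
    secondary_admission: Optional[bool] = None
    transferred_out_within_48h: Optional[bool] = None
    died: Optional[bool] = None
    mof: Optional[bool] = None
    icu_los: Optional[float] = None           # days
    hosp_los: Optional[float] = None          # days
    extras: dict[str, str] = field(default_factory=dict)


#: canonical CSV column order (extras columns are appended after these)
CANONICAL_COLUMNS = [f.name for f in dc_fields(PatientRecord) if f.name != "extras"]

_BOOL_FIELDS = {
    "intubated", "hemothorax", "prbc_transfused",
    "fracture_pelvis", "fracture_femur", "fracture_tibia",
    "secondary_admission", "transferred_out_within_48h", "died", "mof",
}
_INT_FIELDS = {"age", "gcs"}
_FLOAT_FIELDS = {"base_excess", "pao2_fio2", "sbp", "hb", "inr", "icu_los", "hosp_los"}
_CATEGORY_FIELDS = {
    "sex": SEXES,
    "mechanism": MECHANISMS,
    "ecs_motor": ECS_MOTOR,
    "ecs_pupil_size": ECS_BINARY,
    "ecs_pupil_reactivity": ECS_BINARY,
}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # "error" | "warning"
    field: str
    message: str


@dataclass(frozen=True)
class Dialect:
    """Delimiter and missing-token convention of a registry export."""

    delimiter: str = ","
    missing_token: str = "NA"


class RegistryFormatError(ValueError):
    """Raised for unreadable headers or, under strict parsing, bad cells."""


def validate_record(record: PatientRecord) -> list[ValidationIssue]:
    """Check a record's internal consistency.

    Returns an empty list iff every invariant holds.  Inapplicable-but-present
    findings (a Horowitz ratio on a non-intubated patient) are warnings, not
    errors: the value is real, it just cannot contribute to oxygenation scoring.
    """
    issues: list[ValidationIssue] = []

    def err(f: str, msg: str) -> None:
        issues.append(ValidationIssue("error", f, msg))

    if record.age is not None and record.age < 0:
        err("age", f"age must be >= 0, got {record.age}")
    if record.gcs is not None and not (3 <= record.gcs <= 15):
        err("gcs", f"GCS must lie in [3, 15], got {record.gcs}")
    for f, domain in _CATEGORY_FIELDS.items():
        v = getattr(record, f)
        if v is not None and v not in domain:
            err(f, f"unrecognized category {v!r}; expected one of {domain}")
    for f in ("pao2_fio2", "inr"):
        v = getattr(record, f)
        if v is not None and v <= 0:
            err(f, f"{f} must be > 0, got {v}")
    for f in ("sbp", "hb", "icu_los", "hosp_los"):
        v = getattr(record, f)
        if v is not None and v < 0:
            err(f, f"{f} must be >= 0, got {v}")
    if record.ais_items is not None:
        for i, item in enumerate(record.ais_items):
            if item.body_region not in BODY_REGIONS:
                err("ais_items", f"item {i}: unknown body region {item.body_region!r}")
            if not (1 <= item.severity <= 6):
                err("ais_items", f"item {i}: severity {item.severity} outside 1..6")
    if record.pao2_fio2 is not None and record.intubated is False:
        issues.append(ValidationIssue(
            "warning", "pao2_fio2",
            "Horowitz ratio recorded but patient not intubated; value is "
            "inapplicable for oxygenation scoring",
        ))
    return issues


# ---------------------------------------------------------------------------
# cell-level (de)serialization


def _format_cell(name: str, value: object) -> str:
    if value is None:
        return ""
    if name == "ais_items":
        return ";".join(f"{it.body_region}:{it.severity}" for it in value)  # type: ignore[union-attr]
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_cell(name: str, text: str, dialect: Dialect) -> object:
    text = text.strip()
    if text == "" or text == dialect.missing_token:
        return None
    if name == "id":
        return text
    if name == "ais_items":
        items = []
        for part in text.split(";"):
            region, _, sev = part.partition(":")
            items.append(AisItem(region.strip().lower(), int(sev)))
        return items
    if name in _BOOL_FIELDS:
        low = text.lower()
        if low in ("true", "1", "yes", "y"):
            return True
        if low in ("false", "0", "no", "n"):
            return False
        raise ValueError(f"cannot interpret {text!r} as a boolean")
    if name in _INT_FIELDS:
        return int(float(text))
    if name in _FLOAT_FIELDS:
        return float(text)
    if name in _CATEGORY_FIELDS:
        norm = text.strip().lower()
        if norm not in _CATEGORY_FIELDS[name]:
            raise ValueError(f"unrecognized category {text!r}")
        return norm
    raise KeyError(name)


def read_registry(
    path: str | Path,
    dialect: Dialect = Dialect(),
    strict: bool = False,
    issues: Optional[list[str]] = None,
) -> list[PatientRecord]:
    """Read a registry CSV/TSV into patient records.

    Empty cells and ``dialect.missing_token`` map to absent fields.  Columns
    not in the canonical schema are preserved verbatim in ``extras``.  Rows
    with unparseable cells or invariant violations are skipped with a logged
    report under lenient parsing (default) and raise
    :class:`RegistryFormatError` under ``strict=True``.  A list passed as
    ``issues`` collects the per-row reports either way.
    """
    path = Path(path)
    collected = issues if issues is not None else []
    records: list[PatientRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise RegistryFormatError(f"{path}: missing header row") from None
        header = [h.strip() for h in header]
        if not any(h in CANONICAL_COLUMNS for h in header):
            raise RegistryFormatError(
                f"{path}: header names no known record column; got {header}")
        for rownum, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            rec = PatientRecord()
            problems: list[str] = []
            for col, cell in zip(header, row):
                if col in CANONICAL_COLUMNS:
                    try:
                        setattr(rec, col, _parse_cell(col, cell, dialect))
                    except (ValueError, KeyError) as exc:
                        problems.append(f"row {rownum}, column {col!r}: {exc}")
                else:
                    if cell.strip() not in ("", dialect.missing_token):
                        rec.extras[col] = cell.strip()
            if not problems:
                problems.extend(
                    f"row {rownum}, column {i.field!r}: {i.message}"
                    for i in validate_record(rec) if i.severity == "error"
                )
            if problems:
                collected.extend(problems)
                if strict:
                    raise RegistryFormatError("; ".join(problems))
                logger.warning("skipping %s: %s", path.name, "; ".join(problems))
                continue
            records.append(rec)
    return records


def write_registry(
    records: Iterable[PatientRecord],
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    """Write records to CSV/TSV; round-trip safe with :func:`read_registry`.

    Column order is the canonical field order followed by the sorted union of
    extras keys, so output is byte-stable for a given cohort.
    """
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extras})
    header = CANONICAL_COLUMNS + extra_cols
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            row = [_format_cell(c, getattr(rec, c)) for c in CANONICAL_COLUMNS]
            row += [rec.extras.get(c, "") for c in extra_cols]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# cohort inclusion / exclusion


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort filter: adults (>= 16 y) with relevant trauma (ISS >= 9) and a
    major fracture (pelvis, femur or tibia), excluding secondary admissions
    and early (< 48 h) transfers out."""

    min_age: int = 16
    min_iss: int = 9
    require_major_fracture: bool = True
    exclude_secondary_admission: bool = True
    exclude_early_transfer: bool = True

    def __post_init__(self) -> None:
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        if not (1 <= self.min_iss <= 75):
            raise ValueError("min_iss must lie in [1, 75]")


@dataclass(frozen=True)
class Exclusion:
    record: PatientRecord
    reason: str


def default_iss_lookup(record: PatientRecord) -> Optional[int]:
    """ISS from the record: computed from AIS items when present, otherwise a
    recorded ``iss`` passthrough column, otherwise None."""
    if record.ais_items is not None:
        from .comparators import iss  # local import: comparators depends on records

        return iss(record.ais_items)
    raw = record.extras.get("iss")
    if raw is not None:
        try:
            return int(float(raw))
        except ValueError:
            return None
    return None


def apply_inclusion_filter(
    records: Iterable[PatientRecord],
    criteria: InclusionCriteria = InclusionCriteria(),
    iss_lookup: Callable[[PatientRecord], Optional[int]] = default_iss_lookup,
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Partition records into (kept, excluded-with-reason).

    Checks run in a fixed order — age, ISS, major fracture, secondary
    admission, early transfer — and the first failing check names the
    exclusion reason.  A record whose ISS cannot be obtained is excluded with
    reason ``"iss_unavailable"``; a record with unknown age cannot be
    confirmed adult and is excluded with reason ``"age"``.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if rec.age is None or rec.age < criteria.min_age:
            excluded.append(Exclusion(rec, "age"))
            continue
        iss_value = iss_lookup(rec)
        if iss_value is None:
            excluded.append(Exclusion(rec, "iss_unavailable"))
            continue
        if iss_value < criteria.min_iss:
            excluded.append(Exclusion(rec, "iss"))
            continue
        if criteria.require_major_fracture and not (
            rec.fracture_pelvis or rec.fracture_femur or rec.fracture_tibia
        ):
            excluded.append(Exclusion(rec, "fracture"))
            continue
        if criteria.exclude_secondary_admission and rec.secondary_admission:
            excluded.append(Exclusion(rec, "secondary_admission"))
            continue
        if criteria.exclude_early_transfer and rec.transferred_out_within_48h:
            excluded.append(Exclusion(rec, "early_transfer"))
            continue
        kept.append(rec)
    return kept, excluded


def record_equal(a: PatientRecord, b: PatientRecord) -> bool:
    """Field-for-field equality, treating NaN floats as equal to themselves."""
    for f in dc_fields(PatientRecord):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if isinstance(va, float) and isinstance(vb, float):
            if not (va == vb or (math.isnan(va) and math.isnan(vb))):
                return False
        elif va != vb:
            return False
    return True


__all__ = [
    "AisItem",
    "PatientRecord",
    "ValidationIssue",
    "Dialect",
    "InclusionCriteria",
    "Exclusion",
    "RegistryFormatError",
    "CANONICAL_COLUMNS",
    "BODY_REGIONS",
    "read_registry",
    "write_registry",
    "validate_record",
    "apply_inclusion_filter",
    "default_iss_lookup",
    "record_equal",
]
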