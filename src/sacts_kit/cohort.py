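"""Cohort domain model: patients, radiographic findings, outcomes, CSV ingestion.

The unit of analysis is a single blunt-chest-trauma patient presenting to an
emergency department, described by demographics (age, sex, mechanism of
injury), a ventilation flag, a final disposition, and five structured chest
X-ray findings (rib-fracture count, bilaterality, pulmonary-contusion grade,
pneumothorax, haemothorax).  Disposition acts as an outcome surrogate: ICU
admission, palliative T-piece ("poor outcome") and death count as *critical*;
ward admission and discharge count as *non-critical*.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


class ValidationError(ValueError):
    """A record or cell violates the cohort schema."""


class SchemaError(ValidationError):
    """The input file is structurally unusable (e.g. missing columns)."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Mechanism(str, enum.Enum):
    MOTOR_VEHICLE_ACCIDENT = "motor_vehicle_accident"
    PEDESTRIAN_VEHICLE_ACCIDENT = "pedestrian_vehicle_accident"
    FALL_FROM_HEIGHT = "fall_from_height"
    ASSAULT = "assault"
    UNKNOWN = "unknown"


class Disposition(str, enum.Enum):
    DISCHARGED = "discharged"
    WARD = "ward"
    ICU = "icu"
    POOR_OUTCOME = "poor_outcome"
    DEATH = "death"


class ContusionGrade(str, enum.Enum):
    """Pulmonary contusion on CXR: laterality crossed with <50% / >50% opacity."""

    NONE = "none"
    UNILATERAL_MINOR = "unilateral_minor"
    BILATERAL_MINOR = "bilateral_minor"
    UNILATERAL_MAJOR = "unilateral_major"
    BILATERAL_MAJOR = "bilateral_major"


class OutcomeLabel(str, enum.Enum):
    CRITICAL = "critical"
    NON_CRITICAL = "non_critical"


#: dispositions counted as a critical outcome
CRITICAL_DISPOSITIONS = frozenset(
    {Disposition.DEATH, Disposition.POOR_OUTCOME, Disposition.ICU}
)


def classify_outcome(disposition: Disposition | str) -> OutcomeLabel:
    """Map a final disposition onto the binary critical / non-critical outcome.

    ICU, palliative T-piece (poor outcome) and in-department death are
    critical; ward admission and discharge are non-critical.
    """
    try:
        disposition = Disposition(disposition)
    except ValueError:
        raise ValidationError(f"unknown disposition level: {disposition!r}") from None
    if disposition in CRITICAL_DISPOSITIONS:
        return OutcomeLabel.CRITICAL
    return OutcomeLabel.NON_CRITICAL


@dataclass(frozen=True)
class RadiographicFindings:
    """The five structured CXR variables consumed by the trauma scores."""

    rib_fracture_count: int
    bilateral_rib_fractures: bool
    contusion_grade: ContusionGrade
    pneumothorax: bool
    haemothorax: bool

    def __post_init__(self) -> None:
        if not isinstance(self.rib_fracture_count, int) or isinstance(
            self.rib_fracture_count, bool
        ):
            raise ValidationError(
                f"rib_fracture_count must be an integer, got {self.rib_fracture_count!r}"
            )
        if self.rib_fracture_count < 0:
            raise ValidationError(
                f"rib_fracture_count must be >= 0, got {self.rib_fracture_count}"
            )
        if self.bilateral_rib_fractures and self.rib_fracture_count < 2:
            raise ValidationError(
                "bilateral rib fractures require rib_fracture_count >= 2 "
                f"(got {self.rib_fracture_count})"
            )
        object.__setattr__(
            self, "contusion_grade", ContusionGrade(self.contusion_grade)
        )


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: demographics, clinical fields and CXR findings."""

    patient_id: str
    age_years: int
    sex: Sex
    mechanism: Mechanism
    ventilated: bool
    disposition: Disposition
    findings: RadiographicFindings

    def __post_init__(self) -> None:
        if not isinstance(self.age_years, int) or isinstance(self.age_years, bool):
            raise ValidationError(f"age_years must be an integer, got {self.age_years!r}")
        if self.age_years < 18:
            raise ValidationError(
                f"age_years must be >= 18 (adult cohort), got {self.age_years}"
            )
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        object.__setattr__(self, "disposition", Disposition(self.disposition))

    @property
    def outcome(self) -> OutcomeLabel:
        return classify_outcome(self.disposition)


#: CSV schema, in canonical column order.
CSV_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "mechanism",
    "ventilated",
    "disposition",
    "rib_fracture_count",
    "bilateral_rib_fractures",
    "contusion_grade",
    "pneumothorax",
    "haemothorax",
)

_BOOL_VALUES = {"true": True, "false": False}


def _parse_bool(value: str, column: str) -> bool:
    try:
        return _BOOL_VALUES[value.strip().lower()]
    except KeyError:
        raise ValidationError(f"{column}: expected true/false, got {value!r}") from None


def _parse_int(value: str, column: str) -> int:
    try:
        return int(value.strip())
    except ValueError:
        raise ValidationError(f"{column}: expected an integer, got {value!r}") from None


@dataclass(frozen=True)
class RejectedRow:
    """A CSV row that failed validation, with its 1-based data row number."""

    row_number: int
    reason: str


def record_from_row(row: dict[str, str]) -> PatientRecord:
    """Build a validated :class:`PatientRecord` from one CSV row dict."""
    missing = [c for c in CSV_COLUMNS if not (row.get(c) or "").strip()]
    if missing:
        raise ValidationError(f"missing value(s) for: {', '.join(missing)}")
    findings = RadiographicFindings(
        rib_fracture_count=_parse_int(row["rib_fracture_count"], "rib_fracture_count"),
        bilateral_rib_fractures=_parse_bool(
            row["bilateral_rib_fractures"], "bilateral_rib_fractures"
        ),
        contusion_grade=_parse_enum(row["contusion_grade"], ContusionGrade, "contusion_grade"),
        pneumothorax=_parse_bool(row["pneumothorax"], "pneumothorax"),
        haemothorax=_parse_bool(row["haemothorax"], "haemothorax"),
    )
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        age_years=_parse_int(row["age_years"], "age_years"),
        sex=_parse_enum(row["sex"], Sex, "sex"),
        mechanism=_parse_enum(row["mechanism"], Mechanism, "mechanism"),
        ventilated=_parse_bool(row["ventilated"], "ventilated"),
        disposition=_parse_enum(row["disposition"], Disposition, "disposition"),
        findings=findings,
    )


def _parse_enum(value: str, enum_cls: type[enum.Enum], column: str):
    try:
        return enum_cls(value.strip().lower())
    except ValueError:
        levels = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"{column}: {value!r} is not one of [{levels}]"
        ) from None


def parse_cohort_csv(
    path: str | Path, strict: bool = False
) -> tuple[list[PatientRecord], list[RejectedRow]]:
    """Read a cohort CSV, validating each row.

    Rows violating the schema are rejected with a reason (mirroring the
    exclusion of incomplete records from a hand-curated triage register);
    in ``strict`` mode the first rejection aborts the parse.

    Returns ``(records, rejections)``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing_cols = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing_cols:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(sorted(missing_cols))}"
            )
        records: list[PatientRecord] = []
        rejected: list[RejectedRow] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(record_from_row(row))
            except ValidationError as exc:
                if strict:
                    raise ValidationError(f"row {i}: {exc}") from exc
                rejected.append(RejectedRow(row_number=i, reason=str(exc)))
    return records, rejected


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records in the canonical cohort CSV schema."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            f = r.findings
            writer.writerow(
                [
                    r.patient_id,
                    r.age_years,
                    r.sex.value,
                    r.mechanism.value,
                    str(r.ventilated).lower(),
                    r.disposition.value,
                    f.rib_fracture_count,
                    str(f.bilateral_rib_fractures).lower(),
                    f.contusion_grade.value,
                    str(f.pneumothorax).lower(),
                    str(f.haemothorax).lower(),
                ]
            )


def write_rejection_report(rejections: Sequence[RejectedRow], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "reason"])
        for rej in rejections:
            writer.writerow([rej.row_number, rej.reason])


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def age_band(age_years: int) -> str:
    """Age band used by the conventional score: <45, 45-65 (inclusive), >65."""
    if age_years < 45:
        return "<45"
    if age_years <= 65:
        return "45-65"
    return ">65"


def rib_band(count: int) -> str:
    """Rib-fracture count band: 0, 1-2, 3-5 (inclusive), >5."""
    if count == 0:
        return "0"
    if count <= 2:
        return "1-2"
    if count <= 5:
        return "3-5"
    return ">5"


@dataclass(frozen=True)
class CohortSummary:
    """Per-variable level counts and percentages for a cohort.

    ``tables`` maps variable name -> ordered list of (level, count, percent);
    percentages are 100*count/n rounded to one decimal.
    """

    n: int
    tables: dict[str, list[tuple[str, int, float]]]

    def counts(self, variable: str) -> dict[str, int]:
        return {level: count for level, count, _ in self.tables[variable]}


_SUMMARY_LEVELS: dict[str, list[str]] = {
    "sex": [s.value for s in Sex],
    "age_band": ["<45", "45-65", ">65"],
    "mechanism": [m.value for m in Mechanism],
    "outcome": [o.value for o in OutcomeLabel],
    "disposition": [d.value for d in Disposition],
    "ventilated": ["no", "yes"],
    "rib_band": ["0", "1-2", "3-5", ">5"],
    "bilateral_rib_fractures": ["no", "yes"],
    "contusion_grade": [g.value for g in ContusionGrade],
    "pneumothorax": ["no", "yes"],
    "haemothorax": ["no", "yes"],
}


def _level_of(record: PatientRecord, variable: str) -> str:
    f = record.findings
    match variable:
        case "sex":
            return record.sex.value
        case "age_band":
            return age_band(record.age_years)
        case "mechanism":
            return record.mechanism.value
        case "outcome":
            return record.outcome.value
        case "disposition":
            return record.disposition.value
        case "ventilated":
            return "yes" if record.ventilated else "no"
        case "rib_band":
            return rib_band(f.rib_fracture_count)
        case "bilateral_rib_fractures":
            return "yes" if f.bilateral_rib_fractures else "no"
        case "contusion_grade":
            return f.contusion_grade.value
        case "pneumothorax":
            return "yes" if f.pneumothorax else "no"
        case "haemothorax":
            return "yes" if f.haemothorax else "no"
    raise KeyError(variable)


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Tabulate level counts and percentages for every summary variable."""
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(records)
    tables: dict[str, list[tuple[str, int, float]]] = {}
    for variable, levels in _SUMMARY_LEVELS.items():
        counter = Counter(_level_of(r, variable) for r in records)
        tables[variable] = [
            (level, counter.get(level, 0), round(100.0 * counter.get(level, 0) / n, 1))
            for level in levels
        ]
    return CohortSummary(n=n, tables=tables)
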