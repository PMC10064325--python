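"""Claims-domain model: dispensing records, resident stays, clinical events.

The pipeline consumes flat CSV extracts of pharmacy-reimbursement claims —
one file each for drug dispensings, resident stays and non-drug clinical
events (urine cultures, flu vaccines).  This module holds the typed records,
the CSV readers/writers, and dataset-level validation.  Malformed rows are
never silently dropped: every rejected row is reported in a
:class:`ValidationReport`, and ``unknown`` is an explicit enum member rather
than an imputed value, so every denominator stays auditable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ATC_PATTERN",
    "Route",
    "Sex",
    "EventType",
    "DispensingRecord",
    "ResidentStay",
    "ClinicalEvent",
    "ClaimsDataset",
    "RowIssue",
    "ValidationReport",
    "CsvDialect",
    "SchemaError",
    "read_dispensings",
    "read_stays",
    "read_events",
    "write_dispensings",
    "write_stays",
    "write_events",
    "write_dataset",
    "load_dataset",
    "validate_dataset",
]

#: ATC codes are hierarchical: 1 letter (anatomical group), 2 digits, then
#: optional letter, letter, 2-digit suffixes — valid lengths 3, 4, 5 and 7.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}(?:[A-Z](?:[A-Z](?:\d{2})?)?)?$")


def is_valid_atc(code: str) -> bool:
    return bool(ATC_PATTERN.match(code))


class Route(str, Enum):
    """Administration route of a dispensed drug."""

    ORAL = "oral"
    IV = "IV"
    IM = "IM"
    SC = "SC"
    OTHER = "other"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "U"


class EventType(str, Enum):
    URINE_CULTURE = "urine_culture"
    FLU_VACCINE = "flu_vaccine"


@dataclass(frozen=True)
class DispensingRecord:
    """One reimbursed drug dispensing (the pipeline's counting unit).

    ``n_packages`` is the number of packages dispensed; package counts are
    the only quantity information available in reimbursement claims, so
    treatment durations are later *estimated* from them.
    """

    record_id: str
    resident_id: str
    facility_id: str
    dispense_date: date
    atc_code: str
    route: Route = Route.UNKNOWN
    n_packages: int = 1
    units_per_package: Optional[int] = None
    prescriber_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not is_valid_atc(self.atc_code):
            raise ValueError(f"invalid ATC code: {self.atc_code!r}")
        if self.n_packages < 1:
            raise ValueError("n_packages must be >= 1")
        if self.units_per_package is not None and self.units_per_package < 1:
            raise ValueError("units_per_package must be >= 1 when present")


@dataclass(frozen=True)
class ResidentStay:
    """A resident's presence interval in one facility (closed interval).

    ``exit_date`` may be ``None`` for an open (ongoing) stay; downstream
    exposure computations truncate open stays at the analysis-period end.
    """

    resident_id: str
    facility_id: str
    entry_date: date
    exit_date: Optional[date] = None
    sex: Sex = Sex.UNKNOWN
    birth_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.exit_date is not None and self.entry_date > self.exit_date:
            raise ValueError("entry_date after exit_date")


@dataclass(frozen=True)
class ClinicalEvent:
    """A non-drug claim event linked to a resident (urine culture, flu shot)."""

    resident_id: str
    facility_id: str
    event_date: date
    event_type: EventType


@dataclass(frozen=True)
class RowIssue:
    """One validation finding, tied to a source table and record/row id."""

    table: str
    record_id: str
    rule: str
    message: str
    severity: str = "error"  # "error" excludes/fails; "warning" annotates


@dataclass
class ValidationReport:
    n_records: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def merge(self, other: "ValidationReport") -> None:
        for k, v in other.n_records.items():
            self.n_records[k] = self.n_records.get(k, 0) + v
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)

    def summary(self) -> str:
        lines = [
            "validation: " + ("PASS" if self.passed else "FAIL"),
            "records: " + ", ".join(f"{k}={v}" for k, v in sorted(self.n_records.items())),
            f"errors: {len(self.errors)}, warnings: {len(self.warnings)}",
        ]
        for issue in self.errors:
            lines.append(f"  ERROR [{issue.table}:{issue.record_id}] {issue.rule}: {issue.message}")
        for issue in self.warnings:
            lines.append(f"  WARN  [{issue.table}:{issue.record_id}] {issue.rule}: {issue.message}")
        return "\n".join(lines)


@dataclass
class ClaimsDataset:
    """All claims tables for one analysis year (plus optional look-back rows)."""

    dispensings: list
    stays: list
    events: list
    analysis_year: int

    def resident_sex(self) -> dict:
        """Map resident_id -> Sex, taken from the first informative stay row."""
        out: dict = {}
        for stay in self.stays:
            if stay.resident_id not in out or out[stay.resident_id] is Sex.UNKNOWN:
                out[stay.resident_id] = stay.sex
        return out

    def facility_ids(self) -> list:
        ids = {s.facility_id for s in self.stays}
        ids.update(d.facility_id for d in self.dispensings)
        ids.update(e.facility_id for e in self.events)
        return sorted(ids)

    def deduplicated(self) -> "ClaimsDataset":
        """Drop repeat dispensing rows with identical (resident, facility, ATC, date).

        Claims extracts legitimately contain same-day repeat dispensings, so
        this is opt-in (the ``--dedupe`` pipeline flag), never the default.
        """
        seen: set = set()
        keep = []
        for rec in self.dispensings:
            key = (rec.resident_id, rec.facility_id, rec.atc_code, rec.dispense_date)
            if key not in seen:
                seen.add(key)
                keep.append(rec)
        return ClaimsDataset(keep, list(self.stays), list(self.events), self.analysis_year)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

DISPENSING_COLUMNS = [
    "record_id", "resident_id", "facility_id", "dispense_date",
    "atc_code", "route", "n_packages", "units_per_package", "prescriber_id",
]
STAY_COLUMNS = ["resident_id", "facility_id", "entry_date", "exit_date", "sex", "birth_year"]
EVENT_COLUMNS = ["resident_id", "facility_id", "event_date", "event_type"]


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


@dataclass(frozen=True)
class CsvDialect:
    """Input-dialect overrides; claims extracts vary in date formatting."""

    date_format: Optional[str] = None  # strptime format; None means ISO-8601

    def parse_date(self, text: str) -> date:
        if self.date_format is None:
            return date.fromisoformat(text)
        return datetime.strptime(text, self.date_format).date()


_ROUTE_ALIASES = {
    "oral": Route.ORAL, "po": Route.ORAL,
    "iv": Route.IV, "im": Route.IM, "sc": Route.SC,
    "other": Route.OTHER,
    "": Route.UNKNOWN, "unknown": Route.UNKNOWN, "na": Route.UNKNOWN,
}

_SEX_ALIASES = {
    "f": Sex.FEMALE, "female": Sex.FEMALE, "w": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE,
    "": Sex.UNKNOWN, "u": Sex.UNKNOWN, "unknown": Sex.UNKNOWN,
}


def _open_reader(path, columns, table: str) -> tuple:
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    header = reader.fieldnames or []
    missing = [c for c in columns if c not in header]
    if missing:
        fh.close()
        raise SchemaError(f"{table}: missing mandatory column(s): {', '.join(missing)}")
    return fh, reader


def read_dispensings(path, dialect: Optional[CsvDialect] = None):
    """Read dispensings.csv -> (records, issues).

    Unparseable rows are excluded and reported as row-level issues, never
    silently dropped; unknown routes map to :attr:`Route.UNKNOWN`.
    """
    dialect = dialect or CsvDialect()
    records: list = []
    issues: list = []
    fh, reader = _open_reader(path, DISPENSING_COLUMNS, "dispensings")
    with fh:
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("record_id") or f"line{lineno}").strip()
            try:
                d = dialect.parse_date(row["dispense_date"].strip())
            except ValueError:
                issues.append(RowIssue("dispensings", rid, "invalid_date",
                                       f"unparseable date {row['dispense_date']!r}"))
                continue
            atc = row["atc_code"].strip().upper()
            if not is_valid_atc(atc):
                issues.append(RowIssue("dispensings", rid, "invalid_atc",
                                       f"unparseable ATC code {row['atc_code']!r}"))
                continue
            route_raw = (row.get("route") or "").strip()
            route = _ROUTE_ALIASES.get(route_raw.lower())
            if route is None:
                route = Route.UNKNOWN
                issues.append(RowIssue("dispensings", rid, "unrecognized_route",
                                       f"route {route_raw!r} mapped to unknown",
                                       severity="warning"))
            try:
                n_packages = int(row["n_packages"])
                upp_raw = (row.get("units_per_package") or "").strip()
                upp = int(upp_raw) if upp_raw else None
                rec = DispensingRecord(
                    record_id=rid,
                    resident_id=row["resident_id"].strip(),
                    facility_id=row["facility_id"].strip(),
                    dispense_date=d,
                    atc_code=atc,
                    route=route,
                    n_packages=n_packages,
                    units_per_package=upp,
                    prescriber_id=(row.get("prescriber_id") or "").strip() or None,
                )
            except ValueError as exc:
                issues.append(RowIssue("dispensings", rid, "invalid_field", str(exc)))
                continue
            records.append(rec)
    return records, issues


def read_stays(path, dialect: Optional[CsvDialect] = None):
    """Read stays.csv -> (records, issues); empty exit_date means an open stay."""
    dialect = dialect or CsvDialect()
    records: list = []
    issues: list = []
    fh, reader = _open_reader(path, STAY_COLUMNS, "stays")
    with fh:
        for lineno, row in enumerate(reader, start=2):
            rid = f"{row.get('resident_id', '?').strip()}@line{lineno}"
            try:
                entry = dialect.parse_date(row["entry_date"].strip())
                exit_raw = (row.get("exit_date") or "").strip()
                exit_d = dialect.parse_date(exit_raw) if exit_raw else None
            except ValueError:
                issues.append(RowIssue("stays", rid, "invalid_date", "unparseable date"))
                continue
            sex = _SEX_ALIASES.get((row.get("sex") or "").strip().lower(), Sex.UNKNOWN)
            by_raw = (row.get("birth_year") or "").strip()
            try:
                stay = ResidentStay(
                    resident_id=row["resident_id"].strip(),
                    facility_id=row["facility_id"].strip(),
                    entry_date=entry,
                    exit_date=exit_d,
                    sex=sex,
                    birth_year=int(by_raw) if by_raw else None,
                )
            except ValueError as exc:
                issues.append(RowIssue("stays", rid, "entry_after_exit", str(exc)))
                continue
            records.append(stay)
    return records, issues


def read_events(path, dialect: Optional[CsvDialect] = None):
    """Read events.csv -> (records, issues)."""
    dialect = dialect or CsvDialect()
    records: list = []
    issues: list = []
    fh, reader = _open_reader(path, EVENT_COLUMNS, "events")
    with fh:
        for lineno, row in enumerate(reader, start=2):
            rid = f"{row.get('resident_id', '?').strip()}@line{lineno}"
            try:
                d = dialect.parse_date(row["event_date"].strip())
            except ValueError:
                issues.append(RowIssue("events", rid, "invalid_date", "unparseable date"))
                continue
            try:
                etype = EventType(row["event_type"].strip())
            except ValueError:
                issues.append(RowIssue("events", rid, "invalid_event_type",
                                       f"unknown event_type {row['event_type']!r}"))
                continue
            records.append(ClinicalEvent(
                resident_id=row["resident_id"].strip(),
                facility_id=row["facility_id"].strip(),
                event_date=d,
                event_type=etype,
            ))
    return records, issues


def _iso(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_dispensings(records: Iterable[DispensingRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DISPENSING_COLUMNS)
        for r in records:
            w.writerow([
                r.record_id, r.resident_id, r.facility_id, _iso(r.dispense_date),
                r.atc_code, r.route.value, r.n_packages,
                r.units_per_package if r.units_per_package is not None else "",
                r.prescriber_id or "",
            ])


def write_stays(records: Iterable[ResidentStay], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(STAY_COLUMNS)
        for s in records:
            w.writerow([
                s.resident_id, s.facility_id, _iso(s.entry_date), _iso(s.exit_date),
                s.sex.value, s.birth_year if s.birth_year is not None else "",
            ])


def write_events(records: Iterable[ClinicalEvent], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in records:
            w.writerow([e.resident_id, e.facility_id, _iso(e.event_date), e.event_type.value])


def write_dataset(dataset: ClaimsDataset, out_dir) -> dict:
    """Write the three CSV tables into *out_dir*; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dispensings": out_dir / "dispensings.csv",
        "stays": out_dir / "stays.csv",
        "events": out_dir / "events.csv",
    }
    write_dispensings(dataset.dispensings, paths["dispensings"])
    write_stays(dataset.stays, paths["stays"])
    write_events(dataset.events, paths["events"])
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(dataset: ClaimsDataset) -> ValidationReport:
    """Cross-table consistency checks.

    Errors (fail the dataset): duplicate dispensing record_ids, overlapping
    stays of one resident within one facility.  Warnings: dispensings or
    events for residents with no stay record, or dated outside every
    recorded stay of that resident.
    """
    report = ValidationReport(n_records={
        "dispensings": len(dataset.dispensings),
        "stays": len(dataset.stays),
        "events": len(dataset.events),
    })

    seen_ids: set = set()
    for rec in dataset.dispensings:
        if rec.record_id in seen_ids:
            report.errors.append(RowIssue("dispensings", rec.record_id,
                                          "duplicate_record_id", "record_id occurs more than once"))
        seen_ids.add(rec.record_id)

    stays_by_resident: dict = {}
    for stay in dataset.stays:
        stays_by_resident.setdefault(stay.resident_id, []).append(stay)

    for resident_id, stays in stays_by_resident.items():
        by_fac: dict = {}
        for s in stays:
            by_fac.setdefault(s.facility_id, []).append(s)
        for fac, fstays in by_fac.items():
            fstays = sorted(fstays, key=lambda s: s.entry_date)
            for a, b in zip(fstays, fstays[1:]):
                a_exit = a.exit_date or date.max
                if b.entry_date <= a_exit:
                    report.errors.append(RowIssue(
                        "stays", resident_id, "overlapping_stays",
                        f"stays overlap in facility {fac} around {b.entry_date.isoformat()}"))

    def covered(resident_id: str, when: date) -> bool:
        for s in stays_by_resident.get(resident_id, ()):
            if s.entry_date <= when <= (s.exit_date or date.max):
                return True
        return False

    for rec in dataset.dispensings:
        if rec.resident_id not in stays_by_resident:
            report.warnings.append(RowIssue("dispensings", rec.record_id,
                                            "no_stay_record", "resident has no stay record"))
        elif not covered(rec.resident_id, rec.dispense_date):
            report.warnings.append(RowIssue("dispensings", rec.record_id,
                                            "outside_recorded_stay",
                                            "dispensing dated outside every recorded stay"))
    for i, ev in enumerate(dataset.events):
        eid = f"{ev.resident_id}#{i}"
        if ev.resident_id not in stays_by_resident:
            report.warnings.append(RowIssue("events", eid, "no_stay_record",
                                            "resident has no stay record"))
        elif not covered(ev.resident_id, ev.event_date):
            report.warnings.append(RowIssue("events", eid, "outside_recorded_stay",
                                            "event dated outside every recorded stay"))
    return report


def load_dataset(dispensings_path, stays_path, events_path, analysis_year: int,
                 dialect: Optional[CsvDialect] = None):
    """Read all three tables and validate; -> (ClaimsDataset, ValidationReport).

    Row-level parse failures are errors in the report (and the rows are
    excluded from the dataset); the cross-table checks of
    :func:`validate_dataset` are merged in.
    """
    dispensings, disp_issues = read_dispensings(dispensings_path, dialect)
    stays, stay_issues = read_stays(stays_path, dialect)
    events, event_issues = read_events(events_path, dialect)
    dataset = ClaimsDataset(dispensings, stays, events, analysis_year)
    report = validate_dataset(dataset)
    read_issues = disp_issues + stay_issues + event_issues
    report.errors = [i for i in read_issues if i.severity == "error"] + report.errors
    report.warnings = [i for i in read_issues if i.severity == "warning"] + report.warnings
    return dataset, report
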