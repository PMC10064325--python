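"""Quantity metrics (QM1-QM14): volume of antibiotic use for one
facility-year, from pharmacy-claims dispensings.

The counting unit is one dispensing row (one drug, one date); the exposure
denominator is resident-days, counted inclusively over calendar days of the
analysis year.  Rate metrics are expressed per 100 resident-days, share
metrics (QM3, QM12, QM14) on a 0-100 scale.

===== ==========================================================
QM1   J01 dispensings / 100 resident-days
QM2   J01 DDDs / 100 resident-days
QM3   % residents with >=1 J01 dispensing in the year
QM4   amoxicillin/clavulanate dispensings / 100 resident-days
QM5   amoxicillin/clavulanate DDDs / 100 resident-days
QM6   cephalosporin dispensings / 100 resident-days
QM7   cephalosporin DDDs / 100 resident-days
QM8   quinolone dispensings / 100 resident-days
QM9   quinolone DDDs / 100 resident-days
QM10  MLSK dispensings / 100 resident-days
QM11  MLSK DDDs / 100 resident-days
QM12  % parenteral among oral+parenteral J01 dispensings
QM13  urine cultures / 100 resident-days
QM14  % residents with >=1 urine culture in the year
===== ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

from .atc import (
    DddReference,
    DrugClass,
    MissingAtcError,
    RouteCategory,
    in_class,
    load_default_ddd_reference,
    route_category,
    total_ddd,
)
from .claims import ClaimsDataset, ClinicalEvent, EventType, ResidentStay

__all__ = [
    "QM_IDS",
    "Period",
    "IndicatorValue",
    "year_period",
    "cold_periods",
    "hot_period",
    "in_cold_season",
    "resident_days",
    "residents_in_year",
    "residents_present",
    "compute_qm",
    "compute_all_qms",
]

QM_IDS = tuple(f"QM{i}" for i in range(1, 15))


@dataclass(frozen=True)
class Period:
    """A closed calendar interval; both endpoints count."""

    start: date
    end: date
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("period start after end")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def year_period(year: int) -> Period:
    return Period(date(year, 1, 1), date(year, 12, 31), str(year))


def cold_periods(year: int) -> tuple:
    """Cold-weather season: January-March and October-December."""
    return (
        Period(date(year, 1, 1), date(year, 3, 31), "cold"),
        Period(date(year, 10, 1), date(year, 12, 31), "cold"),
    )


def hot_period(year: int) -> Period:
    """Hot-weather season: April-September."""
    return Period(date(year, 4, 1), date(year, 9, 30), "hot")


def in_cold_season(d: date) -> bool:
    return d.month in (1, 2, 3, 10, 11, 12)


@dataclass(frozen=True)
class IndicatorValue:
    """One computed indicator with its numerator/denominator audit trail.

    ``value`` is None when the denominator is zero (or below the
    suppression threshold); the reason is carried in ``flags``.
    """

    indicator_id: str
    facility_id: str
    value: Optional[float]
    numerator: float
    denominator: float
    flags: tuple = ()

    @property
    def defined(self) -> bool:
        return self.value is not None


# ---------------------------------------------------------------------------
# Denominators
# ---------------------------------------------------------------------------

def _overlap_days(stay: ResidentStay, period: Period) -> int:
    """Inclusive day count of stay ∩ period; same-day entry/exit = 1 day."""
    start = max(stay.entry_date, period.start)
    end = min(stay.exit_date or period.end, period.end)
    return (end - start).days + 1 if start <= end else 0


def resident_days(stays: Iterable[ResidentStay], facility_id: str, period: Period) -> int:
    """Total days residents were present in the facility during the period.

    Open-ended stays are truncated at the period end.
    """
    return sum(_overlap_days(s, period) for s in stays if s.facility_id == facility_id)


def residents_present(stays: Iterable[ResidentStay], facility_id: str, period: Period) -> set:
    """Distinct residents with at least one stay-day in the period."""
    return {
        s.resident_id
        for s in stays
        if s.facility_id == facility_id and _overlap_days(s, period) > 0
    }


def residents_in_year(stays: Iterable[ResidentStay], facility_id: str, period: Period) -> int:
    """Count of distinct residents present >=1 day, regardless of stay length."""
    return len(residents_present(stays, facility_id, period))


# ---------------------------------------------------------------------------
# Quantity metrics
# ---------------------------------------------------------------------------

# rate QMs: (drug class, use DDDs instead of counts)
_RATE_QMS = {
    "QM1": (DrugClass.ALL_ABX, False),
    "QM2": (DrugClass.ALL_ABX, True),
    "QM4": (DrugClass.AMC, False),
    "QM5": (DrugClass.AMC, True),
    "QM6": (DrugClass.CEPH, False),
    "QM7": (DrugClass.CEPH, True),
    "QM8": (DrugClass.FQ, False),
    "QM9": (DrugClass.FQ, True),
    "QM10": (DrugClass.MLSK, False),
    "QM11": (DrugClass.MLSK, True),
}


def _facility_year_dispensings(dataset: ClaimsDataset, facility_id: str, period: Period):
    return [
        r for r in dataset.dispensings
        if r.facility_id == facility_id and period.contains(r.dispense_date)
    ]


def _facility_year_events(dataset: ClaimsDataset, facility_id: str, period: Period,
                          event_type: EventType):
    return [
        e for e in dataset.events
        if e.facility_id == facility_id and e.event_type is event_type
        and period.contains(e.event_date)
    ]


def _make_value(qm_id: str, facility_id: str, numerator: float, denominator: float,
                scale: float, flags: tuple, suppression_threshold: float) -> IndicatorValue:
    if denominator <= suppression_threshold:
        reason = "zero_denominator" if denominator == 0 else "denominator_suppressed"
        return IndicatorValue(qm_id, facility_id, None, numerator, denominator,
                              flags + (reason,))
    return IndicatorValue(qm_id, facility_id, scale * numerator / denominator,
                          numerator, denominator, flags)


def compute_qm(dataset: ClaimsDataset, facility_id: str, year: int, qm_id: str,
               *, ddd_ref: Optional[DddReference] = None,
               suppression_threshold: float = 0) -> IndicatorValue:
    """Compute one quantity metric for a facility-year.

    DDD-based metrics need *ddd_ref* (the shipped default is used when
    omitted); dispensings whose ATC code is missing from the reference are
    excluded from the DDD numerator and surfaced in a coverage flag.
    """
    if qm_id not in QM_IDS:
        raise ValueError(f"unknown quantity metric: {qm_id!r}")
    period = year_period(year)
    flags: tuple = ()

    if qm_id in _RATE_QMS:
        drug_class, use_ddd = _RATE_QMS[qm_id]
        records = [r for r in _facility_year_dispensings(dataset, facility_id, period)
                   if in_class(r, drug_class)]
        if use_ddd:
            ref = ddd_ref or load_default_ddd_reference()
            numerator = 0.0
            missing = []
            for r in records:
                try:
                    numerator += total_ddd(r, ref)
                except MissingAtcError:
                    missing.append(r.atc_code)
            if missing:
                flags += tuple(sorted({f"ddd_missing:{c}" for c in missing}))
        else:
            numerator = len(records)
        denominator = resident_days(dataset.stays, facility_id, period)
        return _make_value(qm_id, facility_id, numerator, denominator, 100.0,
                           flags, suppression_threshold)

    if qm_id == "QM3" or qm_id == "QM14":
        present = residents_present(dataset.stays, facility_id, period)
        if qm_id == "QM3":
            exposed = {r.resident_id
                       for r in _facility_year_dispensings(dataset, facility_id, period)
                       if in_class(r, DrugClass.ALL_ABX)}
        else:
            exposed = {e.resident_id
                       for e in _facility_year_events(dataset, facility_id, period,
                                                      EventType.URINE_CULTURE)}
        orphans = exposed - present
        if orphans:
            flags += (f"numerator_residents_without_stay:{len(orphans)}",)
        return _make_value(qm_id, facility_id, len(exposed & present), len(present),
                           100.0, flags, suppression_threshold)

    if qm_id == "QM12":
        j01 = [r for r in _facility_year_dispensings(dataset, facility_id, period)
               if in_class(r, DrugClass.ALL_ABX)]
        oral = sum(route_category(r.route) is RouteCategory.ORAL for r in j01)
        parenteral = sum(route_category(r.route) is RouteCategory.PARENTERAL for r in j01)
        excluded = len(j01) - oral - parenteral
        if excluded:
            flags += (f"route_unknown_excluded:{excluded}",)
        return _make_value(qm_id, facility_id, parenteral, oral + parenteral,
                           100.0, flags, suppression_threshold)

    # QM13: urine cultures per 100 resident-days
    ucs = _facility_year_events(dataset, facility_id, period, EventType.URINE_CULTURE)
    denominator = resident_days(dataset.stays, facility_id, period)
    return _make_value(qm_id, facility_id, len(ucs), denominator, 100.0,
                       flags, suppression_threshold)


def compute_all_qms(dataset: ClaimsDataset, facility_id: str, year: int,
                    *, ddd_ref: Optional[DddReference] = None,
                    suppression_threshold: float = 0) -> list:
    """All 14 quantity metrics, in order QM1..QM14."""
    ref = ddd_ref or load_default_ddd_reference()
    return [
        compute_qm(dataset, facility_id, year, qm_id, ddd_ref=ref,
                   suppression_threshold=suppression_threshold)
        for qm_id in QM_IDS
    ]
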