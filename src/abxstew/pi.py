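"""Proxy indicators (PI1-PI10): appropriateness of antibiotic use estimated
from claims alone, each classified against its consensus target.

====  ======================================================================
PI1   UC-linked UTI drug choice ratio, male residents
      (nitrofurantoin + fosfomycin/trometamol + pivmecillinam + amoxicillin
      + amoxicillin/clavulanate) / (quinolones + cephalosporins + SXT)
PI2   UC-linked UTI drug choice ratio, female residents
      (nitrofurantoin + fosfomycin/trometamol + pivmecillinam) / quinolones
PI3   % quinolone dispensings preceded by another quinolone within 6 months
PI4   seasonal variation of J01 dispensings, (cold/hot - 1) x 100
PI5   seasonal variation of amoxicillin/clavulanate dispensings
PI6   first-line / second-line ratio:
      (amoxicillin + amoxicillin/clavulanate) / (quinolones + cephalosporins
      + MLSK)
PI7   % prolonged courses (estimated duration > 7 days) among eight
      monitored drugs
PI8   % J01 dispensings with a same-day systemic NSAID co-dispensing
PI9   flu vaccines dispensed in the cold season / residents present in the
      cold season, x 100
PI10  % oral among oral+parenteral cephalosporin dispensings
====  ======================================================================

A dispensing is *UC-linked* when the same resident had a urine culture
0-7 days (inclusive, configurable) before the dispensing date.  PI3 uses a
180-day look-back that may reach into the prior calendar year, so datasets
should include a look-back extract; without one the value carries a
completeness warning.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .atc import (
    DrugClass,
    MissingAtcError,
    PackReference,
    RouteCategory,
    estimate_duration_days,
    in_class,
    load_default_pack_reference,
    route_category,
)
from .claims import ClaimsDataset, EventType, Sex
from .qm import (
    IndicatorValue,
    Period,
    cold_periods,
    hot_period,
    in_cold_season,
    residents_present,
    year_period,
)

__all__ = [
    "PI_IDS",
    "DEFAULT_UC_WINDOW_DAYS",
    "DEFAULT_LOOKBACK_DAYS",
    "ComplianceClass",
    "Bound",
    "ComplianceTarget",
    "PIResult",
    "load_default_targets",
    "classify_compliance",
    "pi_uti_choice_ratio",
    "pi_repeat_quinolone",
    "pi_seasonal_variation",
    "pi_first_vs_second_line",
    "pi_prolonged_courses",
    "pi_nsaid_coprescription",
    "pi_flu_coverage",
    "pi_oral_cephalosporins",
    "compute_all_pis",
]

PI_IDS = tuple(f"PI{i}" for i in range(1, 11))

DEFAULT_UC_WINDOW_DAYS = 7
DEFAULT_LOOKBACK_DAYS = 180

#: Prolonged-course threshold: strictly greater than 7.0 estimated days.
PROLONGED_COURSE_DAYS = 7.0

# Sex-specific class sets for the UC-linked UTI choice ratios.
_UTI_NUMERATOR = {
    Sex.MALE: (DrugClass.NITROFURANTOIN, DrugClass.FOSFOMYCIN_TROM,
               DrugClass.PIVMECILLINAM, DrugClass.AMOX, DrugClass.AMC),
    Sex.FEMALE: (DrugClass.NITROFURANTOIN, DrugClass.FOSFOMYCIN_TROM,
                 DrugClass.PIVMECILLINAM),
}
_UTI_DENOMINATOR = {
    Sex.MALE: (DrugClass.FQ, DrugClass.CEPH, DrugClass.SXT),
    Sex.FEMALE: (DrugClass.FQ,),
}


class ComplianceClass(Enum):
    OPTIMAL = "optimal"
    ACCEPTABLE = "acceptable"
    NON_COMPLIANT = "non_compliant"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class Bound:
    op: str    # one of <, <=, >, >=, ==
    value: float

    def satisfied_by(self, x: float) -> bool:
        if self.op == "<":
            return x < self.value
        if self.op == "<=":
            return x <= self.value
        if self.op == ">":
            return x > self.value
        if self.op == ">=":
            return x >= self.value
        if self.op == "==":
            return x == self.value
        raise ValueError(f"unknown comparison operator {self.op!r}")


@dataclass(frozen=True)
class ComplianceTarget:
    """Consensus target for one proxy indicator.

    ``optimal`` and ``acceptable`` bounds are applied in order; strict vs
    inclusive comparison follows the printed target exactly.
    """

    indicator_id: str
    direction: str                       # "lower" or "higher" is better
    optimal: Optional[Bound] = None
    acceptable: Optional[Bound] = None


@dataclass(frozen=True)
class PIResult:
    value: IndicatorValue
    compliance: ComplianceClass


def load_default_targets() -> dict:
    """The shipped encoding of the consensus target bands, keyed PI1..PI10."""
    raw = yaml.safe_load(
        resources.files("abxstew.data").joinpath("targets.yaml").read_text(encoding="utf-8"))
    return load_targets_mapping(raw)


def load_targets_mapping(raw: Mapping) -> dict:
    targets = {}
    for pid, row in raw.items():
        targets[pid] = ComplianceTarget(
            indicator_id=pid,
            direction=row["direction"],
            optimal=Bound(row["optimal"]["op"], float(row["optimal"]["value"]))
            if "optimal" in row else None,
            acceptable=Bound(row["acceptable"]["op"], float(row["acceptable"]["value"]))
            if "acceptable" in row else None,
        )
    return targets


def load_targets_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return load_targets_mapping(yaml.safe_load(fh) or {})


def classify_compliance(value: IndicatorValue, target: ComplianceTarget) -> ComplianceClass:
    """Three-band classification (optimal / acceptable / non-compliant).

    Undefined indicator values classify undefined; when no acceptable bound
    exists the classification is two-band (optimal else non-compliant).
    """
    if value.value is None:
        return ComplianceClass.UNDEFINED
    if target.optimal is not None and target.optimal.satisfied_by(value.value):
        return ComplianceClass.OPTIMAL
    if target.acceptable is not None and target.acceptable.satisfied_by(value.value):
        return ComplianceClass.ACCEPTABLE
    return ComplianceClass.NON_COMPLIANT


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _year_dispensings(dataset: ClaimsDataset, facility_id: str, period: Period):
    return [r for r in dataset.dispensings
            if r.facility_id == facility_id and period.contains(r.dispense_date)]


def _ratio_value(pi_id: str, facility_id: str, numerator: float, denominator: float,
                 scale: float, flags: tuple = ()) -> IndicatorValue:
    if denominator == 0:
        return IndicatorValue(pi_id, facility_id, None, numerator, denominator,
                              flags + ("zero_denominator",))
    return IndicatorValue(pi_id, facility_id, scale * numerator / denominator,
                          numerator, denominator, flags)


def _uc_dates_by_resident(dataset: ClaimsDataset, facility_id: str) -> dict:
    out: dict = {}
    for e in dataset.events:
        if e.facility_id == facility_id and e.event_type is EventType.URINE_CULTURE:
            out.setdefault(e.resident_id, []).append(e.event_date)
    return out


def _uc_linked(record, uc_dates: dict, window_days: int) -> bool:
    """True iff the resident had a urine culture 0..window days before."""
    for uc in uc_dates.get(record.resident_id, ()):
        if 0 <= (record.dispense_date - uc).days <= window_days:
            return True
    return False


# ---------------------------------------------------------------------------
# The ten proxy indicators
# ---------------------------------------------------------------------------

def pi_uti_choice_ratio(dataset: ClaimsDataset, facility_id: str, year: int, sex: Sex,
                        uc_window_days: int = DEFAULT_UC_WINDOW_DAYS) -> IndicatorValue:
    """PI1 (male) / PI2 (female): drug-choice ratio among UC-linked dispensings.

    Both numerator and denominator are restricted to dispensings in the week
    following a urine culture of the same resident; plain ratio (no x100).
    """
    if sex not in (Sex.MALE, Sex.FEMALE):
        raise ValueError("sex must be male or female for the UTI choice ratio")
    pi_id = "PI1" if sex is Sex.MALE else "PI2"
    period = year_period(year)
    sex_of = dataset.resident_sex()
    uc_dates = _uc_dates_by_resident(dataset, facility_id)
    num_classes = _UTI_NUMERATOR[sex]
    den_classes = _UTI_DENOMINATOR[sex]
    numerator = denominator = 0
    for r in _year_dispensings(dataset, facility_id, period):
        if sex_of.get(r.resident_id) is not sex:
            continue
        if not _uc_linked(r, uc_dates, uc_window_days):
            continue
        if any(in_class(r, c) for c in num_classes):
            numerator += 1
        elif any(in_class(r, c) for c in den_classes):
            denominator += 1
    return _ratio_value(pi_id, facility_id, numerator, denominator, 1.0)


def pi_repeat_quinolone(dataset: ClaimsDataset, facility_id: str, year: int,
                        lookback_days: int = DEFAULT_LOOKBACK_DAYS) -> IndicatorValue:
    """PI3: % of the year's quinolone dispensings preceded by another
    quinolone of the same resident within the preceding 6 months (1-180
    days strictly before)."""
    period = year_period(year)
    fq_by_resident: dict = {}
    for r in dataset.dispensings:
        if r.facility_id == facility_id and in_class(r, DrugClass.FQ):
            fq_by_resident.setdefault(r.resident_id, []).append(r.dispense_date)
    year_fq = [r for r in _year_dispensings(dataset, facility_id, period)
               if in_class(r, DrugClass.FQ)]
    numerator = 0
    for r in year_fq:
        for prev in fq_by_resident.get(r.resident_id, ()):
            if 1 <= (r.dispense_date - prev).days <= lookback_days:
                numerator += 1
                break
    flags: tuple = ()
    if not any(d.dispense_date < period.start for d in dataset.dispensings):
        flags = ("no_lookback_data",)
    return _ratio_value("PI3", facility_id, numerator, len(year_fq), 100.0, flags)


def pi_seasonal_variation(dataset: ClaimsDataset, facility_id: str, year: int,
                          class_id: DrugClass) -> IndicatorValue:
    """PI4 (all J01) / PI5 (amoxicillin/clavulanate): (cold/hot - 1) x 100.

    Cold season is January-March plus October-December of the analysis
    year; the numerator/denominator fields carry the raw cold and hot
    counts (the value is not a plain scaled ratio).
    """
    if class_id not in (DrugClass.ALL_ABX, DrugClass.AMC):
        raise ValueError("seasonal variation is defined for ALL_ABX and AMC only")
    pi_id = "PI4" if class_id is DrugClass.ALL_ABX else "PI5"
    period = year_period(year)
    cold = hot = 0
    for r in _year_dispensings(dataset, facility_id, period):
        if not in_class(r, class_id):
            continue
        if in_cold_season(r.dispense_date):
            cold += 1
        else:
            hot += 1
    if hot == 0:
        return IndicatorValue(pi_id, facility_id, None, cold, hot, ("zero_denominator",))
    return IndicatorValue(pi_id, facility_id, (cold / hot - 1.0) * 100.0, cold, hot)


def pi_first_vs_second_line(dataset: ClaimsDataset, facility_id: str, year: int) -> IndicatorValue:
    """PI6: (amoxicillin + amoxicillin/clavulanate) / (quinolones +
    cephalosporins + MLSK); plain ratio."""
    period = year_period(year)
    numerator = denominator = 0
    for r in _year_dispensings(dataset, facility_id, period):
        if in_class(r, DrugClass.AMOX) or in_class(r, DrugClass.AMC):
            numerator += 1
        elif (in_class(r, DrugClass.FQ) or in_class(r, DrugClass.CEPH)
              or in_class(r, DrugClass.MLSK)):
            denominator += 1
    return _ratio_value("PI6", facility_id, numerator, denominator, 1.0)


def pi_prolonged_courses(dataset: ClaimsDataset, facility_id: str, year: int,
                         pack_ref: Optional[PackReference] = None) -> IndicatorValue:
    """PI7: % of dispensings of the eight monitored drugs whose estimated
    duration strictly exceeds 7.0 days (a 7.0-day course is not prolonged)."""
    ref = pack_ref or load_default_pack_reference()
    period = year_period(year)
    numerator = denominator = 0
    flags: tuple = ()
    missing = []
    for r in _year_dispensings(dataset, facility_id, period):
        if not in_class(r, DrugClass.PI7_LIST):
            continue
        try:
            duration = estimate_duration_days(r, ref)
        except MissingAtcError:
            missing.append(r.atc_code)
            continue
        denominator += 1
        if duration > PROLONGED_COURSE_DAYS:
            numerator += 1
    if missing:
        flags += tuple(sorted({f"pack_missing:{c}" for c in missing}))
    return _ratio_value("PI7", facility_id, numerator, denominator, 100.0, flags)


def pi_nsaid_coprescription(dataset: ClaimsDataset, facility_id: str, year: int) -> IndicatorValue:
    """PI8: % of J01 dispensings with a same-day systemic NSAID dispensing
    for the same resident."""
    period = year_period(year)
    records = _year_dispensings(dataset, facility_id, period)
    nsaid_days = {(r.resident_id, r.dispense_date)
                  for r in records if in_class(r, DrugClass.NSAID)}
    j01 = [r for r in records if in_class(r, DrugClass.ALL_ABX)]
    numerator = sum((r.resident_id, r.dispense_date) in nsaid_days for r in j01)
    return _ratio_value("PI8", facility_id, numerator, len(j01), 100.0)


def pi_flu_coverage(dataset: ClaimsDataset, facility_id: str, year: int) -> IndicatorValue:
    """PI9: flu vaccines dispensed in the cold season per 100 residents
    present in the cold season.

    Counts vaccine *dispensings* (flu_vaccine events, or dispensings in the
    influenza-vaccine ATC class J07BB), so repeat doses can push the value
    above 100; that is flagged rather than capped.
    """
    cold = cold_periods(year)
    n_vaccines = sum(
        1 for e in dataset.events
        if e.facility_id == facility_id and e.event_type is EventType.FLU_VACCINE
        and any(p.contains(e.event_date) for p in cold))
    n_vaccines += sum(
        1 for r in dataset.dispensings
        if r.facility_id == facility_id and in_class(r, DrugClass.FLU_VACCINE)
        and any(p.contains(r.dispense_date) for p in cold))
    residents = set()
    for p in cold:
        residents |= residents_present(dataset.stays, facility_id, p)
    value = _ratio_value("PI9", facility_id, n_vaccines, len(residents), 100.0)
    if value.value is not None and value.value > 100.0:
        value = IndicatorValue(value.indicator_id, value.facility_id, value.value,
                               value.numerator, value.denominator,
                               value.flags + ("over_coverage",))
    return value


def pi_oral_cephalosporins(dataset: ClaimsDataset, facility_id: str, year: int) -> IndicatorValue:
    """PI10: % oral among oral+parenteral cephalosporin dispensings;
    route-unknown cephalosporins are excluded from both terms."""
    period = year_period(year)
    oral = parenteral = excluded = 0
    for r in _year_dispensings(dataset, facility_id, period):
        if not in_class(r, DrugClass.CEPH):
            continue
        cat = route_category(r.route)
        if cat is RouteCategory.ORAL:
            oral += 1
        elif cat is RouteCategory.PARENTERAL:
            parenteral += 1
        else:
            excluded += 1
    flags = (f"route_unknown_excluded:{excluded}",) if excluded else ()
    return _ratio_value("PI10", facility_id, oral, oral + parenteral, 100.0, flags)


def compute_all_pis(dataset: ClaimsDataset, facility_id: str, year: int,
                    *, pack_ref: Optional[PackReference] = None,
                    targets: Optional[Mapping] = None,
                    uc_window_days: int = DEFAULT_UC_WINDOW_DAYS,
                    lookback_days: int = DEFAULT_LOOKBACK_DAYS) -> list:
    """All ten proxy indicators with their compliance classes, PI1..PI10."""
    targets = targets or load_default_targets()
    values = [
        pi_uti_choice_ratio(dataset, facility_id, year, Sex.MALE, uc_window_days),
        pi_uti_choice_ratio(dataset, facility_id, year, Sex.FEMALE, uc_window_days),
        pi_repeat_quinolone(dataset, facility_id, year, lookback_days),
        pi_seasonal_variation(dataset, facility_id, year, DrugClass.ALL_ABX),
        pi_seasonal_variation(dataset, facility_id, year, DrugClass.AMC),
        pi_first_vs_second_line(dataset, facility_id, year),
        pi_prolonged_courses(dataset, facility_id, year, pack_ref),
        pi_nsaid_coprescription(dataset, facility_id, year),
        pi_flu_coverage(dataset, facility_id, year),
        pi_oral_cephalosporins(dataset, facility_id, year),
    ]
    return [PIResult(v, classify_compliance(v, targets[v.indicator_id])) for v in values]
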