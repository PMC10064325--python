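"""Shared fixtures: the hand-enumerated composite facility, reference
tables, and a random micro-dataset builder for oracle comparisons."""

import random
from datetime import date, timedelta

import pytest

from abxstew.atc import load_default_ddd_reference, load_default_pack_reference
from abxstew.claims import (
    ClaimsDataset,
    ClinicalEvent,
    DispensingRecord,
    EventType,
    ResidentStay,
    Route,
    Sex,
)
from abxstew.pi import load_default_targets


@pytest.fixture(scope="session")
def ddd_ref():
    return load_default_ddd_reference()


@pytest.fixture(scope="session")
def pack_ref():
    return load_default_pack_reference()


@pytest.fixture(scope="session")
def targets():
    return load_default_targets()


def _disp(rid, resident, day, atc, route=Route.ORAL, packs=1, upp=None):
    return DispensingRecord(record_id=rid, resident_id=resident, facility_id="F1",
                            dispense_date=day, atc_code=atc, route=route,
                            n_packages=packs, units_per_package=upp)


@pytest.fixture()
def composite_dataset():
    """Six residents, one facility, year 2019; every indicator exercised.

    All 24 values are hand-enumerated in the acceptance tests:
    1369 resident-days, 13 antibiotic dispensings in the year (8 cold-season,
    5 hot-season), one look-back quinolone, 4 urine cultures, 4 flu vaccines.
    """
    stays = [
        ResidentStay("r1", "F1", date(2019, 1, 1), date(2019, 12, 31), Sex.MALE, 1930),
        ResidentStay("r2", "F1", date(2019, 1, 1), date(2019, 12, 31), Sex.FEMALE, 1931),
        ResidentStay("r3", "F1", date(2019, 1, 1), date(2019, 12, 31), Sex.FEMALE, 1935),
        ResidentStay("r4", "F1", date(2019, 1, 1), date(2019, 6, 30), Sex.MALE, 1928),
        ResidentStay("r5", "F1", date(2019, 10, 1), date(2019, 12, 31), Sex.FEMALE, 1933),
        ResidentStay("r6", "F1", date(2019, 7, 1), date(2019, 7, 1), Sex.MALE, 1940),
    ]
    events = [
        ClinicalEvent("r1", "F1", date(2019, 2, 1), EventType.URINE_CULTURE),
        ClinicalEvent("r2", "F1", date(2019, 3, 10), EventType.URINE_CULTURE),
        ClinicalEvent("r2", "F1", date(2019, 7, 1), EventType.URINE_CULTURE),
        ClinicalEvent("r4", "F1", date(2019, 5, 1), EventType.URINE_CULTURE),
        ClinicalEvent("r1", "F1", date(2019, 11, 15), EventType.FLU_VACCINE),
        ClinicalEvent("r2", "F1", date(2019, 11, 15), EventType.FLU_VACCINE),
        ClinicalEvent("r3", "F1", date(2019, 1, 20), EventType.FLU_VACCINE),
        ClinicalEvent("r5", "F1", date(2019, 10, 20), EventType.FLU_VACCINE),
    ]
    dispensings = [
        # UC-linked choices (PI1/PI2)
        _disp("d01", "r1", date(2019, 2, 3), "J01XE01", packs=1, upp=21),   # nitrofurantoin
        _disp("d02", "r4", date(2019, 5, 4), "J01MA01", packs=1, upp=10),   # ofloxacin
        _disp("d03", "r2", date(2019, 3, 11), "J01XX01", packs=1, upp=1),   # fosfomycin
        _disp("d04", "r2", date(2019, 7, 3), "J01MA02", packs=1, upp=10),   # ciprofloxacin
        # cephalosporins (PI10: 3 oral + 1 IV)
        _disp("d05", "r3", date(2019, 1, 15), "J01DC02", packs=2, upp=10),
        _disp("d06", "r3", date(2019, 11, 10), "J01DD13", packs=1, upp=10),
        _disp("d07", "r1", date(2019, 6, 10), "J01DC02", packs=1, upp=10),
        _disp("d08", "r4", date(2019, 2, 20), "J01DD13", Route.IV, packs=1, upp=10),
        # aminopenicillins (PI6 numerator); d09 has unknown route (QM12 excl.)
        _disp("d09", "r5", date(2019, 10, 15), "J01CA04", Route.UNKNOWN, packs=1, upp=14),
        _disp("d10", "r2", date(2019, 4, 10), "J01CA04", packs=2, upp=14),
        _disp("d11", "r1", date(2019, 12, 5), "J01CR02", packs=1, upp=14),
        _disp("d12", "r3", date(2019, 5, 20), "J01CR02", packs=2, upp=14),
        # MLSK
        _disp("d13", "r4", date(2019, 3, 15), "J01FA09", packs=1, upp=14),
        # same-day NSAID with d12 (PI8)
        _disp("d14", "r3", date(2019, 5, 20), "M01AE01", packs=1, upp=20),
        # look-back quinolone for PI3 (140 days before d02)
        _disp("d15", "r4", date(2018, 12, 15), "J01MA01", packs=1, upp=10),
    ]
    return ClaimsDataset(dispensings, stays, events, analysis_year=2019)


#: Hand-enumerated truth for the composite fixture (value, numerator, denominator).
COMPOSITE_EXPECTED = {
    "QM1": (100 * 13 / 1369, 13, 1369),
    "QM2": (100 * 99.25 / 1369, 99.25, 1369),
    "QM3": (100 * 5 / 6, 5, 6),
    "QM4": (100 * 2 / 1369, 2, 1369),
    "QM5": (100 * 28.0 / 1369, 28.0, 1369),
    "QM6": (100 * 4 / 1369, 4, 1369),
    "QM7": (100 * 20.0 / 1369, 20.0, 1369),
    "QM8": (100 * 2 / 1369, 2, 1369),
    "QM9": (100 * 10.0 / 1369, 10.0, 1369),
    "QM10": (100 * 1 / 1369, 1, 1369),
    "QM11": (100 * 7.0 / 1369, 7.0, 1369),
    "QM12": (100 * 1 / 12, 1, 12),
    "QM13": (100 * 4 / 1369, 4, 1369),
    "QM14": (100 * 3 / 6, 3, 6),
    "PI1": (1.0, 1, 1),
    "PI2": (1.0, 1, 1),
    "PI3": (50.0, 1, 2),
    "PI4": (60.0, 8, 5),
    "PI5": (0.0, 1, 1),
    "PI6": (4 / 7, 4, 7),
    "PI7": (30.0, 3, 10),
    "PI8": (100 * 1 / 13, 1, 13),
    "PI9": (80.0, 4, 5),
    "PI10": (75.0, 3, 4),
}

COMPOSITE_COMPLIANCE = {
    "PI1": "non_compliant", "PI2": "non_compliant", "PI3": "non_compliant",
    "PI4": "non_compliant", "PI5": "optimal", "PI6": "non_compliant",
    "PI7": "non_compliant", "PI8": "non_compliant", "PI9": "non_compliant",
    "PI10": "non_compliant",
}


# ---------------------------------------------------------------------------
# Random micro-datasets for oracle comparisons
# ---------------------------------------------------------------------------

_RANDOM_ATCS = [
    "J01CA04", "J01CR02", "J01CA08", "J01DC02", "J01DD13", "J01MA01", "J01MA02",
    "J01FA06", "J01FA09", "J01FG01", "J01XE01", "J01XX01", "J01EE01", "J01AA02",
    "M01AE01", "N02BE01", "J05AB01", "J07BB02",
]
_RANDOM_ROUTES = [Route.ORAL, Route.ORAL, Route.ORAL, Route.IV, Route.IM,
                  Route.SC, Route.OTHER, Route.UNKNOWN]


def make_random_dataset(seed, year=2019, max_records=200):
    """A small random claims dataset exercising edge cases.

    Residents keep a consistent sex across stays; dates span the look-back
    and the analysis year; routes include unknown/other; some dispensings
    omit units_per_package and some ATC codes are outside every indicator
    class.
    """
    rng = random.Random(seed)
    facilities = ["f1", "f2"]
    y0 = date(year, 1, 1)
    stays, dispensings, events = [], [], []
    sex_of = {}
    for fac in facilities:
        for i in range(rng.randint(2, 8)):
            rid = f"{fac}-p{i}"
            sex_of[rid] = rng.choice([Sex.FEMALE, Sex.MALE, Sex.UNKNOWN])
            start = y0 + timedelta(days=rng.randint(-200, 330))
            length = rng.randint(0, 500)
            exit_d = start + timedelta(days=length)
            if rng.random() < 0.2:
                exit_d = None
            stays.append(ResidentStay(rid, fac, start, exit_d, sex_of[rid],
                                      rng.randint(1920, 1945)))
    residents = [s.resident_id for s in stays]
    n_disp = rng.randint(5, max_records - 40)
    for k in range(n_disp):
        rid = rng.choice(residents)
        fac = rid.split("-")[0]
        day = y0 + timedelta(days=rng.randint(-180, 364))
        dispensings.append(DispensingRecord(
            record_id=f"d{k}", resident_id=rid, facility_id=fac,
            dispense_date=day, atc_code=rng.choice(_RANDOM_ATCS),
            route=rng.choice(_RANDOM_ROUTES), n_packages=rng.randint(1, 3),
            units_per_package=rng.choice([None, 1, 10, 14, 21]),
        ))
    for k in range(rng.randint(0, 25)):
        rid = rng.choice(residents)
        fac = rid.split("-")[0]
        day = y0 + timedelta(days=rng.randint(0, 364))
        events.append(ClinicalEvent(
            rid, fac, day,
            rng.choice([EventType.URINE_CULTURE, EventType.URINE_CULTURE,
                        EventType.FLU_VACCINE])))
    return ClaimsDataset(dispensings, stays, events, analysis_year=year)
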