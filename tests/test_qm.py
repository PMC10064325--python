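"""Quantity metrics: denominators, per-metric examples, invariants."""

import random
from datetime import date

import pytest

from abxstew.claims import (
    ClaimsDataset,
    ClinicalEvent,
    DispensingRecord,
    EventType,
    ResidentStay,
    Route,
    Sex,
)
from abxstew.qm import (
    QM_IDS,
    Period,
    compute_all_qms,
    compute_qm,
    resident_days,
    residents_in_year,
    year_period,
)
from conftest import make_random_dataset

Y2019 = year_period(2019)


def _stay(rid, start, end, fac="f1", sex=Sex.FEMALE):
    return ResidentStay(rid, fac, start, end, sex)


class TestResidentDays:
    def test_full_year_is_365(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 12, 31))]
        assert resident_days(stays, "f1", Y2019) == 365

    def test_inclusive_endpoints(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 1, 10)),
                 _stay("p2", date(2019, 1, 5), date(2019, 1, 6))]
        assert resident_days(stays, "f1", Y2019) == 12

    def test_same_day_entry_exit_counts_one_day(self):
        stays = [_stay("p1", date(2019, 7, 1), date(2019, 7, 1))]
        assert resident_days(stays, "f1", Y2019) == 1

    def test_stay_outside_period_counts_zero(self):
        stays = [_stay("p1", date(2018, 1, 1), date(2018, 12, 31))]
        assert resident_days(stays, "f1", Y2019) == 0

    def test_open_exit_truncated_at_period_end(self):
        stays = [_stay("p1", date(2019, 12, 1), None)]
        assert resident_days(stays, "f1", Y2019) == 31

    def test_other_facility_not_counted(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 12, 31), fac="f2")]
        assert resident_days(stays, "f1", Y2019) == 0


class TestResidentsInYear:
    def test_single_day_resident_counts(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 12, 31)),
                 _stay("p2", date(2019, 1, 1), date(2019, 12, 31)),
                 _stay("p3", date(2019, 7, 1), date(2019, 7, 1))]
        assert residents_in_year(stays, "f1", Y2019) == 3

    def test_no_stays_is_zero(self):
        assert residents_in_year([], "f1", Y2019) == 0

    def test_two_intervals_counted_once(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 3, 1)),
                 _stay("p1", date(2019, 6, 1), date(2019, 8, 1))]
        assert residents_in_year(stays, "f1", Y2019) == 1


def _abx(rid, resident, day, atc="J01CA04", route=Route.ORAL):
    return DispensingRecord(rid, resident, "f1", day, atc, route=route,
                            n_packages=1, units_per_package=14)


class TestComputeQm:
    def test_qm1_three_dispensings_730_resident_days(self):
        """Two full-year residents and three antibiotic dispensings."""
        ds = ClaimsDataset(
            [_abx(f"d{i}", "p1", date(2019, 3, 1 + i)) for i in range(3)],
            [_stay("p1", date(2019, 1, 1), date(2019, 12, 31)),
             _stay("p2", date(2019, 1, 1), date(2019, 12, 31))],
            [], 2019)
        v = compute_qm(ds, "f1", 2019, "QM1")
        assert v.numerator == 3 and v.denominator == 730
        assert v.value == pytest.approx(100 * 3 / 730)
        assert round(v.value, 4) == 0.4110

    def test_qm3_half_of_residents_on_antibiotics(self):
        stays = [_stay(f"p{i}", date(2019, 1, 1), date(2019, 12, 31)) for i in range(4)]
        ds = ClaimsDataset([_abx("d1", "p0", date(2019, 2, 1)),
                            _abx("d2", "p1", date(2019, 3, 1)),
                            _abx("d3", "p1", date(2019, 9, 1))], stays, [], 2019)
        v = compute_qm(ds, "f1", 2019, "QM3")
        assert v.value == 50.0

    def test_qm12_one_iv_in_ten(self):
        records = [_abx(f"d{i}", "p1", date(2019, 3, 1)) for i in range(9)]
        records.append(_abx("d9", "p1", date(2019, 4, 1), route=Route.IV))
        ds = ClaimsDataset(records,
                           [_stay("p1", date(2019, 1, 1), date(2019, 12, 31))], [], 2019)
        v = compute_qm(ds, "f1", 2019, "QM12")
        assert v.value == 10.0

    def test_qm12_unknown_route_excluded_from_both_terms(self):
        records = [_abx("d0", "p1", date(2019, 3, 1), route=Route.IV),
                   _abx("d1", "p1", date(2019, 3, 2), route=Route.ORAL),
                   _abx("d2", "p1", date(2019, 3, 3), route=Route.UNKNOWN)]
        ds = ClaimsDataset(records,
                           [_stay("p1", date(2019, 1, 1), date(2019, 12, 31))], [], 2019)
        v = compute_qm(ds, "f1", 2019, "QM12")
        assert (v.numerator, v.denominator) == (1, 2)
        assert "route_unknown_excluded:1" in v.flags

    def test_qm13_qm14_urine_cultures(self):
        stays = [_stay("p1", date(2019, 1, 1), date(2019, 12, 31)),
                 _stay("p2", date(2019, 1, 1), date(2019, 12, 31))]
        events = [ClinicalEvent("p1", "f1", date(2019, 5, 1), EventType.URINE_CULTURE),
                  ClinicalEvent("p1", "f1", date(2019, 6, 1), EventType.URINE_CULTURE)]
        ds = ClaimsDataset([], stays, events, 2019)
        assert compute_qm(ds, "f1", 2019, "QM13").value == pytest.approx(100 * 2 / 730)
        assert compute_qm(ds, "f1", 2019, "QM14").value == 50.0

    def test_ddd_missing_code_excluded_with_coverage_flag(self, ddd_ref):
        records = [_abx("d0", "p1", date(2019, 3, 1)),                  # in reference
                   _abx("d1", "p1", date(2019, 3, 2), atc="J01XX02")]   # not in reference
        ds = ClaimsDataset(records,
                           [_stay("p1", date(2019, 1, 1), date(2019, 12, 31))], [], 2019)
        v = compute_qm(ds, "f1", 2019, "QM2", ddd_ref=ddd_ref)
        assert v.numerator == pytest.approx(14 / 1.5)
        assert "ddd_missing:J01XX02" in v.flags

    def test_unknown_qm_id_raises(self, composite_dataset):
        with pytest.raises(ValueError, match="unknown quantity metric"):
            compute_qm(composite_dataset, "F1", 2019, "QM99")

    def test_empty_facility_returns_14_undefined_values(self):
        ds = ClaimsDataset([], [], [], 2019)
        values = compute_all_qms(ds, "nowhere", 2019)
        assert [v.indicator_id for v in values] == list(QM_IDS)
        assert all(v.value is None for v in values)
        assert all("zero_denominator" in v.flags for v in values)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_class_counts_sum_below_total(self, seed, ddd_ref):
        ds = make_random_dataset(seed)
        for fac in ("f1", "f2"):
            qm = {v.indicator_id: v
                  for v in compute_all_qms(ds, fac, 2019, ddd_ref=ddd_ref)}
            assert (qm["QM4"].numerator + qm["QM6"].numerator
                    + qm["QM8"].numerator + qm["QM10"].numerator) <= qm["QM1"].numerator
            assert (qm["QM5"].numerator + qm["QM7"].numerator
                    + qm["QM9"].numerator + qm["QM11"].numerator) <= qm["QM2"].numerator + 1e-9
            for share in ("QM3", "QM12", "QM14"):
                if qm[share].value is not None:
                    assert 0.0 <= qm[share].value <= 100.0

    @pytest.mark.parametrize("seed", range(4))
    def test_permutation_invariance(self, seed, ddd_ref):
        ds = make_random_dataset(seed)
        rng = random.Random(seed + 1)
        shuffled = ClaimsDataset(rng.sample(ds.dispensings, len(ds.dispensings)),
                                 rng.sample(ds.stays, len(ds.stays)),
                                 rng.sample(ds.events, len(ds.events)), 2019)
        for a, b in zip(compute_all_qms(ds, "f1", 2019, ddd_ref=ddd_ref),
                        compute_all_qms(shuffled, "f1", 2019, ddd_ref=ddd_ref)):
            assert a.indicator_id == b.indicator_id
            if a.value is None:
                assert b.value is None
            else:
                assert b.value == pytest.approx(a.value, rel=1e-12)
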