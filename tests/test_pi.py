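"""Proxy indicators: UC linkage, windows, ratios, and target classification."""

from datetime import date, timedelta

import pytest

from abxstew.atc import DrugClass, PackReference, PackEntry
from abxstew.claims import (
    ClaimsDataset,
    ClinicalEvent,
    DispensingRecord,
    EventType,
    ResidentStay,
    Route,
    Sex,
)
from abxstew.pi import (
    PI_IDS,
    ComplianceClass,
    classify_compliance,
    compute_all_pis,
    pi_first_vs_second_line,
    pi_flu_coverage,
    pi_nsaid_coprescription,
    pi_oral_cephalosporins,
    pi_prolonged_courses,
    pi_repeat_quinolone,
    pi_seasonal_variation,
    pi_uti_choice_ratio,
)
from abxstew.qm import IndicatorValue


def _stay(rid, sex=Sex.FEMALE, start=date(2019, 1, 1), end=date(2019, 12, 31)):
    return ResidentStay(rid, "f1", start, end, sex)


def _disp(rid, resident, day, atc, route=Route.ORAL, packs=1, upp=None):
    return DispensingRecord(rid, resident, "f1", day, atc, route=route,
                            n_packages=packs, units_per_package=upp)


def _uc(resident, day):
    return ClinicalEvent(resident, "f1", day, EventType.URINE_CULTURE)


def _ds(dispensings=(), stays=(), events=()):
    return ClaimsDataset(list(dispensings), list(stays), list(events), 2019)


class TestUtiChoiceRatio:
    def test_male_linked_first_choice_over_reserve(self):
        uc = date(2019, 3, 1)
        ds = _ds([_disp("d1", "p1", uc + timedelta(days=3), "J01XE01"),
                  _disp("d2", "p1", uc + timedelta(days=3), "J01MA01")],
                 [_stay("p1", Sex.MALE)], [_uc("p1", uc)])
        v = pi_uti_choice_ratio(ds, "f1", 2019, Sex.MALE)
        assert v.indicator_id == "PI1"
        assert v.value == 1.0

    def test_female_zero_denominator_undefined(self):
        uc = date(2019, 3, 1)
        ds = _ds([_disp("d1", "p1", uc + timedelta(days=1), "J01XX01")],
                 [_stay("p1", Sex.FEMALE)], [_uc("p1", uc)])
        v = pi_uti_choice_ratio(ds, "f1", 2019, Sex.FEMALE)
        assert v.indicator_id == "PI2"
        assert v.value is None
        assert "zero_denominator" in v.flags

    def test_dispensing_eight_days_after_uc_not_linked(self):
        uc = date(2019, 3, 1)
        ds = _ds([_disp("d1", "p1", uc + timedelta(days=8), "J01XE01"),
                  _disp("d2", "p1", uc + timedelta(days=8), "J01MA01")],
                 [_stay("p1", Sex.MALE)], [_uc("p1", uc)])
        v = pi_uti_choice_ratio(ds, "f1", 2019, Sex.MALE)
        assert (v.numerator, v.denominator) == (0, 0)
        assert v.value is None

    def test_window_boundary_day_seven_is_linked(self):
        uc = date(2019, 3, 1)
        ds = _ds([_disp("d1", "p1", uc + timedelta(days=7), "J01MA01"),
                  _disp("d2", "p1", uc, "J01XE01")],
                 [_stay("p1", Sex.MALE)], [_uc("p1", uc)])
        v = pi_uti_choice_ratio(ds, "f1", 2019, Sex.MALE)
        assert (v.numerator, v.denominator) == (1, 1)

    def test_moving_uc_out_of_window_removes_both_terms(self):
        day = date(2019, 6, 10)
        disp = [_disp("d1", "p1", day, "J01XE01"),
                _disp("d2", "p1", day, "J01MA01")]
        stays = [_stay("p1", Sex.MALE)]
        linked = pi_uti_choice_ratio(_ds(disp, stays, [_uc("p1", day - timedelta(days=5))]),
                                     "f1", 2019, Sex.MALE)
        unlinked = pi_uti_choice_ratio(_ds(disp, stays, [_uc("p1", day - timedelta(days=12))]),
                                       "f1", 2019, Sex.MALE)
        assert (linked.numerator, linked.denominator) == (1, 1)
        assert (unlinked.numerator, unlinked.denominator) == (0, 0)

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError, match="male or female"):
            pi_uti_choice_ratio(_ds(), "f1", 2019, Sex.UNKNOWN)


class TestRepeatQuinolone:
    def test_two_courses_61_days_apart(self):
        ds = _ds([_disp("d1", "p1", date(2019, 3, 1), "J01MA01"),
                  _disp("d2", "p1", date(2019, 5, 1), "J01MA01")],
                 [_stay("p1")])
        v = pi_repeat_quinolone(ds, "f1", 2019)
        assert v.value == 50.0

    def test_single_course_is_zero(self):
        ds = _ds([_disp("d1", "p1", date(2019, 3, 1), "J01MA01")], [_stay("p1")])
        assert pi_repeat_quinolone(ds, "f1", 2019).value == 0.0

    def test_gap_beyond_180_days_not_a_repeat(self):
        ds = _ds([_disp("d1", "p1", date(2019, 2, 1), "J01MA01"),
                  _disp("d2", "p1", date(2019, 2, 1) + timedelta(days=200), "J01MA01")],
                 [_stay("p1")])
        assert pi_repeat_quinolone(ds, "f1", 2019).value == 0.0

    def test_lookback_crosses_calendar_year(self):
        ds = _ds([_disp("d0", "p1", date(2018, 12, 1), "J01MA01"),
                  _disp("d1", "p1", date(2019, 1, 15), "J01MA01")],
                 [_stay("p1", start=date(2018, 1, 1))])
        v = pi_repeat_quinolone(ds, "f1", 2019)
        assert v.value == 100.0
        assert "no_lookback_data" not in v.flags

    def test_missing_lookback_flagged(self):
        ds = _ds([_disp("d1", "p1", date(2019, 1, 15), "J01MA01")], [_stay("p1")])
        assert "no_lookback_data" in pi_repeat_quinolone(ds, "f1", 2019).flags


class TestSeasonalVariation:
    def _mk(self, cold, hot, atc="J01CA04"):
        disp = [_disp(f"c{i}", "p1", date(2019, 2, 1), atc) for i in range(cold)]
        disp += [_disp(f"h{i}", "p1", date(2019, 6, 1), atc) for i in range(hot)]
        return _ds(disp, [_stay("p1")])

    def test_twenty_percent_excess(self):
        v = pi_seasonal_variation(self._mk(12, 10), "f1", 2019, DrugClass.ALL_ABX)
        assert v.value == pytest.approx(20.0)

    def test_balanced_seasons_zero(self):
        v = pi_seasonal_variation(self._mk(7, 7), "f1", 2019, DrugClass.ALL_ABX)
        assert v.value == 0.0

    def test_empty_hot_season_undefined(self):
        v = pi_seasonal_variation(self._mk(3, 0), "f1", 2019, DrugClass.ALL_ABX)
        assert v.value is None and "zero_denominator" in v.flags

    def test_amc_variant_ignores_other_antibiotics(self):
        ds = self._mk(4, 2, atc="J01CR02")
        extra = _ds([_disp("x1", "p1", date(2019, 2, 2), "J01CA04")]).dispensings
        ds = ClaimsDataset(ds.dispensings + extra, ds.stays, ds.events, 2019)
        v = pi_seasonal_variation(ds, "f1", 2019, DrugClass.AMC)
        assert v.indicator_id == "PI5"
        assert v.value == pytest.approx(100.0)

    def test_restricted_to_supported_classes(self):
        with pytest.raises(ValueError):
            pi_seasonal_variation(_ds(), "f1", 2019, DrugClass.FQ)


class TestFirstVsSecondLine:
    def test_hand_count(self):
        disp = ([_disp(f"a{i}", "p1", date(2019, 3, 1), "J01CA04") for i in range(3)]
                + [_disp(f"b{i}", "p1", date(2019, 3, 2), "J01CR02") for i in range(2)]
                + [_disp("c0", "p1", date(2019, 3, 3), "J01MA01"),
                   _disp("c1", "p1", date(2019, 3, 4), "J01DC02")])
        v = pi_first_vs_second_line(_ds(disp, [_stay("p1")]), "f1", 2019)
        assert v.value == pytest.approx(2.5)

    def test_no_second_line_undefined(self):
        v = pi_first_vs_second_line(
            _ds([_disp("a0", "p1", date(2019, 3, 1), "J01CA04")], [_stay("p1")]),
            "f1", 2019)
        assert v.value is None

    def test_equal_counts_ratio_one(self):
        disp = ([_disp(f"a{i}", "p1", date(2019, 3, 1), "J01CA04") for i in range(4)]
                + [_disp(f"b{i}", "p1", date(2019, 3, 2), "J01FA09") for i in range(4)])
        assert pi_first_vs_second_line(_ds(disp, [_stay("p1")]), "f1", 2019).value == 1.0


class TestProlongedCourses:
    def test_half_prolonged(self, pack_ref):
        ds = _ds([_disp("d1", "p1", date(2019, 3, 1), "J01CA04", packs=1, upp=14),
                  _disp("d2", "p1", date(2019, 4, 1), "J01CA04", packs=2, upp=14)],
                 [_stay("p1")])
        assert pi_prolonged_courses(ds, "f1", 2019, pack_ref).value == 50.0

    def test_exactly_seven_days_not_prolonged(self, pack_ref):
        ds = _ds([_disp(f"d{i}", "p1", date(2019, 3, 1), "J01CA04", packs=1, upp=14)
                  for i in range(3)], [_stay("p1")])
        assert pi_prolonged_courses(ds, "f1", 2019, pack_ref).value == 0.0

    def test_unmonitored_drug_ignored_entirely(self, pack_ref):
        ds = _ds([_disp("d1", "p1", date(2019, 3, 1), "J01MA01", packs=9, upp=10),
                  _disp("d2", "p1", date(2019, 4, 1), "J01CA04", packs=2, upp=14)],
                 [_stay("p1")])
        v = pi_prolonged_courses(ds, "f1", 2019, pack_ref)
        assert (v.numerator, v.denominator) == (1, 1)

    def test_missing_pack_entry_excluded_with_warning(self):
        sparse = PackReference({"J01CA04": PackEntry(14, 2)})
        ds = _ds([_disp("d1", "p1", date(2019, 3, 1), "J01XE01", packs=2),
                  _disp("d2", "p1", date(2019, 4, 1), "J01CA04", packs=2, upp=14)],
                 [_stay("p1")])
        v = pi_prolonged_courses(ds, "f1", 2019, sparse)
        assert v.denominator == 1
        assert "pack_missing:J01XE01" in v.flags


class TestNsaidCoprescription:
    def test_one_in_four(self):
        day = date(2019, 3, 1)
        disp = [_disp(f"a{i}", "p1", day + timedelta(days=10 * i), "J01CA04")
                for i in range(4)]
        disp.append(_disp("n1", "p1", day, "M01AE01"))
        assert pi_nsaid_coprescription(_ds(disp, [_stay("p1")]), "f1", 2019).value == 25.0

    def test_no_nsaids_is_zero(self):
        ds = _ds([_disp("a0", "p1", date(2019, 3, 1), "J01CA04")], [_stay("p1")])
        assert pi_nsaid_coprescription(ds, "f1", 2019).value == 0.0

    def test_next_day_nsaid_not_counted(self):
        ds = _ds([_disp("a0", "p1", date(2019, 3, 1), "J01CA04"),
                  _disp("n1", "p1", date(2019, 3, 2), "M01AE01")], [_stay("p1")])
        assert pi_nsaid_coprescription(ds, "f1", 2019).value == 0.0


class TestFluCoverage:
    def _cold_residents(self, n):
        return [_stay(f"p{i}") for i in range(n)]

    def test_eighty_percent(self):
        events = [ClinicalEvent(f"p{i}", "f1", date(2019, 11, 5), EventType.FLU_VACCINE)
                  for i in range(8)]
        v = pi_flu_coverage(_ds([], self._cold_residents(10), events), "f1", 2019)
        assert v.value == 80.0

    def test_no_vaccines_zero(self):
        assert pi_flu_coverage(_ds([], self._cold_residents(10), []), "f1", 2019).value == 0.0

    def test_over_coverage_flagged_not_capped(self):
        events = [ClinicalEvent(f"p{i % 10}", "f1", date(2019, 11, 5), EventType.FLU_VACCINE)
                  for i in range(11)]
        v = pi_flu_coverage(_ds([], self._cold_residents(10), events), "f1", 2019)
        assert v.value == pytest.approx(110.0)
        assert "over_coverage" in v.flags

    def test_hot_season_vaccine_not_counted(self):
        events = [ClinicalEvent("p0", "f1", date(2019, 6, 5), EventType.FLU_VACCINE)]
        assert pi_flu_coverage(_ds([], self._cold_residents(2), events), "f1", 2019).value == 0.0

    def test_vaccine_dispensing_by_atc_counts(self):
        disp = [_disp("v1", "p0", date(2019, 11, 5), "J07BB02")]
        v = pi_flu_coverage(_ds(disp, self._cold_residents(2), []), "f1", 2019)
        assert v.value == 50.0


class TestOralCephalosporins:
    def test_three_oral_one_iv(self):
        disp = [_disp(f"c{i}", "p1", date(2019, 3, 1), "J01DC02") for i in range(3)]
        disp.append(_disp("c4", "p1", date(2019, 3, 2), "J01DD13", route=Route.IV))
        assert pi_oral_cephalosporins(_ds(disp, [_stay("p1")]), "f1", 2019).value == 75.0

    def test_parenteral_only_zero(self):
        disp = [_disp("c0", "p1", date(2019, 3, 1), "J01DC02", route=Route.IM)]
        assert pi_oral_cephalosporins(_ds(disp, [_stay("p1")]), "f1", 2019).value == 0.0

    def test_unknown_route_excluded_with_warning(self):
        disp = [_disp("c0", "p1", date(2019, 3, 1), "J01DC02", route=Route.UNKNOWN),
                _disp("c1", "p1", date(2019, 3, 2), "J01DC02")]
        v = pi_oral_cephalosporins(_ds(disp, [_stay("p1")]), "f1", 2019)
        assert (v.numerator, v.denominator) == (1, 1)
        assert "route_unknown_excluded:1" in v.flags


class TestCompliance:
    def _value(self, pi_id, x):
        return IndicatorValue(pi_id, "f1", x, 0, 1)

    def test_undefined_value_classifies_undefined(self, targets):
        v = IndicatorValue("PI7", "f1", None, 0, 0, ("zero_denominator",))
        assert classify_compliance(v, targets["PI7"]) is ComplianceClass.UNDEFINED

    def test_optimal_zero_means_exactly_zero(self, targets):
        assert classify_compliance(self._value("PI8", 0.0),
                                   targets["PI8"]) is ComplianceClass.OPTIMAL
        assert classify_compliance(self._value("PI8", 0.01),
                                   targets["PI8"]) is ComplianceClass.ACCEPTABLE

    @pytest.mark.parametrize("pi_id", ["PI1", "PI3", "PI4", "PI5", "PI7", "PI8", "PI10"])
    def test_monotone_for_lower_better_targets(self, targets, pi_id):
        order = {ComplianceClass.OPTIMAL: 0, ComplianceClass.ACCEPTABLE: 1,
                 ComplianceClass.NON_COMPLIANT: 2}
        ranks = [order[classify_compliance(self._value(pi_id, x), targets[pi_id])]
                 for x in [0.0, 0.05, 0.1, 0.5, 1, 4, 5, 9, 10, 19, 20, 25, 30, 50, 100]]
        assert ranks == sorted(ranks)


class TestComputeAllPis:
    def test_ten_values_in_order(self, composite_dataset):
        results = compute_all_pis(composite_dataset, "F1", 2019)
        assert [r.value.indicator_id for r in results] == list(PI_IDS)

    def test_empty_facility_all_undefined_or_zero_rate(self):
        results = compute_all_pis(_ds(), "f1", 2019)
        assert len(results) == 10
        for r in results:
            assert r.value.value is None
            assert r.compliance is ComplianceClass.UNDEFINED
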