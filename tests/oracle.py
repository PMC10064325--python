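"""Naive per-record reference implementation of all 24 indicators.

Deliberately written as plain double loops with inline literals and no use
of the package's engine modules, so it can serve as an independent oracle
on micro-datasets.  Reference values (DDDs, pack contents) are read
straight from the shipped YAML files with yaml.safe_load, bypassing the
package's reference classes.
"""

from datetime import date, timedelta
from importlib import resources

import yaml

_DDD = yaml.safe_load(
    resources.files("abxstew.data").joinpath("ddd_reference.yaml").read_text())
_PACK = yaml.safe_load(
    resources.files("abxstew.data").joinpath("pack_reference.yaml").read_text())

PI7_CODES = ("J01CA04", "J01CR02", "J01DC02", "J01DD13",
             "J01FA06", "J01FA09", "J01FG01", "J01XE01")


def _days(a, b):
    return (b - a).days + 1 if a <= b else 0


def _in_year(d, year):
    return d.year == year


def _cold(d):
    return d.month in (1, 2, 3, 10, 11, 12)


def _stay_days_in(stay, start, end):
    a = max(stay.entry_date, start)
    b = min(stay.exit_date if stay.exit_date is not None else end, end)
    return _days(a, b)


def oracle_indicators(dataset, facility_id, year, uc_window=7, lookback=180):
    """Compute all 24 indicator values (floats or None) by brute force."""
    y0, y1 = date(year, 1, 1), date(year, 12, 31)
    stays = [s for s in dataset.stays if s.facility_id == facility_id]
    disp_all = [d for d in dataset.dispensings if d.facility_id == facility_id]
    disp = [d for d in disp_all if _in_year(d.dispense_date, year)]
    events = [e for e in dataset.events if e.facility_id == facility_id]
    ucs = [e for e in events
           if e.event_type.value == "urine_culture" and _in_year(e.event_date, year)]

    rd = 0
    present = set()
    for s in stays:
        n = _stay_days_in(s, y0, y1)
        rd += n
        if n > 0:
            present.add(s.resident_id)

    sex = {}
    for s in stays + [s for s in dataset.stays if s.facility_id != facility_id]:
        if s.resident_id not in sex or sex[s.resident_id].value == "U":
            sex[s.resident_id] = s.sex

    out = {}

    def rate(num, den, scale):
        return None if den == 0 else scale * num / den

    j01 = [d for d in disp if d.atc_code.startswith("J01")]
    out["QM1"] = rate(len(j01), rd, 100.0)

    def ddd_sum(records):
        total = 0.0
        for d in records:
            if d.atc_code not in _DDD:
                continue
            row = _DDD[d.atc_code]
            upp = d.units_per_package
            if upp is None:
                upp = row.get("units_per_package")
            if upp is None:
                continue
            total += d.n_packages * upp * row["unit_strength_grams"] / row["ddd_grams"]
        return total

    out["QM2"] = rate(ddd_sum(j01), rd, 100.0)
    abx_residents = {d.resident_id for d in j01} & present
    out["QM3"] = rate(len(abx_residents), len(present), 100.0)

    for qm_count, qm_ddd, prefix in (("QM4", "QM5", "J01CR02"),
                                     ("QM6", "QM7", "J01D"),
                                     ("QM8", "QM9", "J01M"),
                                     ("QM10", "QM11", "J01F")):
        sub = [d for d in j01 if d.atc_code.startswith(prefix)]
        out[qm_count] = rate(len(sub), rd, 100.0)
        out[qm_ddd] = rate(ddd_sum(sub), rd, 100.0)

    oral = [d for d in j01 if d.route.value == "oral"]
    parenteral = [d for d in j01 if d.route.value in ("IV", "IM", "SC")]
    out["QM12"] = rate(len(parenteral), len(oral) + len(parenteral), 100.0)

    out["QM13"] = rate(len(ucs), rd, 100.0)
    uc_residents = {e.resident_id for e in ucs} & present
    out["QM14"] = rate(len(uc_residents), len(present), 100.0)

    # --- proxy indicators -------------------------------------------------
    uc_dates = {}
    for e in events:
        if e.event_type.value == "urine_culture":
            uc_dates.setdefault(e.resident_id, []).append(e.event_date)

    def uc_linked(d):
        for u in uc_dates.get(d.resident_id, []):
            if 0 <= (d.dispense_date - u).days <= uc_window:
                return True
        return False

    for pi_id, wanted_sex, num_codes, den_codes in (
            ("PI1", "M", ("J01XE01", "J01XX01", "J01CA08", "J01CA04", "J01CR02"),
             ("J01M", "J01D", "J01EE01")),
            ("PI2", "F", ("J01XE01", "J01XX01", "J01CA08"), ("J01M",))):
        num = den = 0
        for d in disp:
            s = sex.get(d.resident_id)
            if s is None or s.value != wanted_sex or not uc_linked(d):
                continue
            if any(d.atc_code.startswith(c) for c in num_codes):
                num += 1
            elif any(d.atc_code.startswith(c) for c in den_codes):
                den += 1
        out[pi_id] = rate(num, den, 1.0)

    fq_year = [d for d in disp if d.atc_code.startswith("J01M")]
    num = 0
    for d in fq_year:
        for other in disp_all:
            if (other.resident_id == d.resident_id
                    and other.atc_code.startswith("J01M")
                    and 1 <= (d.dispense_date - other.dispense_date).days <= lookback):
                num += 1
                break
    out["PI3"] = rate(num, len(fq_year), 100.0)

    for pi_id, prefix in (("PI4", "J01"), ("PI5", "J01CR02")):
        cold = len([d for d in disp
                    if d.atc_code.startswith(prefix) and _cold(d.dispense_date)])
        hot = len([d for d in disp
                   if d.atc_code.startswith(prefix) and not _cold(d.dispense_date)])
        out[pi_id] = None if hot == 0 else (cold / hot - 1.0) * 100.0

    first = len([d for d in disp if d.atc_code.startswith("J01CA04")
                 or d.atc_code.startswith("J01CR02")])
    second = len([d for d in disp if d.atc_code.startswith("J01M")
                  or d.atc_code.startswith("J01D") or d.atc_code.startswith("J01F")])
    out["PI6"] = rate(first, second, 1.0)

    num = den = 0
    for d in disp:
        if d.atc_code not in PI7_CODES or d.atc_code not in _PACK:
            continue
        upp = d.units_per_package
        if upp is None:
            upp = _PACK[d.atc_code]["units_per_package"]
        duration = d.n_packages * upp / _PACK[d.atc_code]["units_per_day"]
        den += 1
        if duration > 7.0:
            num += 1
    out["PI7"] = rate(num, den, 100.0)

    nsaid_days = {(d.resident_id, d.dispense_date)
                  for d in disp if d.atc_code.startswith("M01A")}
    num = len([d for d in j01 if (d.resident_id, d.dispense_date) in nsaid_days])
    out["PI8"] = rate(num, len(j01), 100.0)

    flu = len([e for e in events if e.event_type.value == "flu_vaccine"
               and _in_year(e.event_date, year) and _cold(e.event_date)])
    flu += len([d for d in disp if d.atc_code.startswith("J07BB")
                and _cold(d.dispense_date)])
    cold_res = set()
    for s in stays:
        for a, b in ((date(year, 1, 1), date(year, 3, 31)),
                     (date(year, 10, 1), date(year, 12, 31))):
            if _stay_days_in(s, a, b) > 0:
                cold_res.add(s.resident_id)
    out["PI9"] = rate(flu, len(cold_res), 100.0)

    ceph = [d for d in disp if d.atc_code.startswith("J01D")]
    oral_c = len([d for d in ceph if d.route.value == "oral"])
    par_c = len([d for d in ceph if d.route.value in ("IV", "IM", "SC")])
    out["PI10"] = rate(oral_c, oral_c + par_c, 100.0)

    return out
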