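"""Compute all 24 indicators for one small facility-year.

Builds a six-resident facility in memory (stays, urine cultures, flu
vaccines, 14 antibiotic/NSAID dispensings plus one look-back quinolone) and
prints every quantity metric and proxy indicator with its
numerator/denominator and, for proxy indicators, the consensus compliance
class.
"""

from datetime import date

from abxstew import (
    ClaimsDataset,
    ClinicalEvent,
    DispensingRecord,
    EventType,
    ResidentStay,
    Route,
    Sex,
    compute_facility_set,
)


def disp(rid, resident, day, atc, route=Route.ORAL, packs=1, upp=14):
    return DispensingRecord(rid, resident, "F1", day, atc, route=route,
                            n_packages=packs, units_per_package=upp)


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
    disp("d01", "r1", date(2019, 2, 3), "J01XE01", upp=21),    # nitrofurantoin, 2 d after UC
    disp("d02", "r4", date(2019, 5, 4), "J01MA01", upp=10),    # ofloxacin, 3 d after UC
    disp("d03", "r2", date(2019, 3, 11), "J01XX01", upp=1),    # fosfomycin, 1 d after UC
    disp("d04", "r2", date(2019, 7, 3), "J01MA02", upp=10),    # ciprofloxacin, 2 d after UC
    disp("d05", "r3", date(2019, 1, 15), "J01DC02", packs=2, upp=10),
    disp("d06", "r3", date(2019, 11, 10), "J01DD13", upp=10),
    disp("d07", "r1", date(2019, 6, 10), "J01DC02", upp=10),
    disp("d08", "r4", date(2019, 2, 20), "J01DD13", Route.IV, upp=10),
    disp("d09", "r5", date(2019, 10, 15), "J01CA04", Route.UNKNOWN),
    disp("d10", "r2", date(2019, 4, 10), "J01CA04", packs=2),
    disp("d11", "r1", date(2019, 12, 5), "J01CR02"),
    disp("d12", "r3", date(2019, 5, 20), "J01CR02", packs=2),
    disp("d13", "r4", date(2019, 3, 15), "J01FA09"),
    disp("d14", "r3", date(2019, 5, 20), "M01AE01", upp=20),   # ibuprofen, same day as d12
    disp("d15", "r4", date(2018, 12, 15), "J01MA01", upp=10),  # look-back quinolone
]

dataset = ClaimsDataset(dispensings, stays, events, analysis_year=2019)
fset = compute_facility_set(dataset, "F1", 2019)
compliance = fset.compliance()

print("Facility F1, year 2019 — 1369 resident-days over six residents\n")
for v in fset.values():
    val = "undefined" if v.value is None else f"{v.value:8.4f}"
    line = f"{v.indicator_id:>5}: {val}   (num {v.numerator:g} / den {v.denominator:g})"
    if v.indicator_id in compliance:
        line += f"   [{compliance[v.indicator_id].value}]"
    print(line)

print("""
Reading the output: QM1 says this facility dispensed 0.95 antibiotic
prescriptions per 100 resident-days (13 dispensings over 1369 days of
residency); QM12 says 8.3% of route-known antibiotic dispensings were
parenteral. PI3 = 50 means half the year's quinolone dispensings followed
another quinolone within 6 months (one course in late 2018); it exceeds the
acceptable band (<10%), so it is classified non_compliant. PI5 = 0 (equal
amoxicillin/clavulanate use in cold and hot season) meets its <20% target.
""")
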