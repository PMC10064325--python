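"""DDD computation and package-based treatment-duration estimation.

Reimbursement claims record how many packages were dispensed, not how long
the prescribed course was. This example converts dispensings into WHO
defined daily doses (DDDs) and into estimated course durations, the
primitive behind the prolonged-course indicator (>7 estimated days).
"""

from datetime import date

from abxstew import (
    DispensingRecord,
    estimate_duration_days,
    load_default_ddd_reference,
    load_default_pack_reference,
    total_ddd,
)

ddd_ref = load_default_ddd_reference()
pack_ref = load_default_pack_reference()

records = [
    ("amoxicillin 1 g, one box of 14",
     DispensingRecord("a", "p", "f", date(2019, 3, 1), "J01CA04",
                      n_packages=1, units_per_package=14)),
    ("amoxicillin 1 g, two boxes",
     DispensingRecord("b", "p", "f", date(2019, 3, 1), "J01CA04",
                      n_packages=2, units_per_package=14)),
    ("nitrofurantoin 50 mg, one box of 21",
     DispensingRecord("c", "p", "f", date(2019, 3, 1), "J01XE01",
                      n_packages=1, units_per_package=21)),
    ("fosfomycin trometamol 3 g, single sachet",
     DispensingRecord("d", "p", "f", date(2019, 3, 1), "J01XX01",
                      n_packages=1, units_per_package=1)),
]

for label, rec in records:
    ddd = total_ddd(rec, ddd_ref)
    days = estimate_duration_days(rec, pack_ref)
    prolonged = "prolonged (>7 d)" if days > 7.0 else "not prolonged"
    print(f"{label}")
    print(f"    {ddd:5.2f} DDD, estimated {days:4.1f} days -> {prolonged}")

print("""
One 14-tablet box of amoxicillin at 2 tablets/day is a 7.0-day course —
exactly at the boundary, so not prolonged; the second box doubles the
estimate to 14 days and crosses the >7-day threshold.""")
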