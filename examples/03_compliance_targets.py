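"""Classify proxy-indicator values against the consensus targets.

Shows the three-band (optimal / acceptable / non-compliant) and two-band
classification, with the strict-vs-inclusive comparisons the targets print
(e.g. prolonged courses: optimal <5%, acceptable <20%).
"""

from abxstew import IndicatorValue, classify_compliance, load_default_targets

targets = load_default_targets()

probes = [
    ("PI7", 4.2, "prolonged antibiotic courses (%)"),
    ("PI7", 12.0, "prolonged antibiotic courses (%)"),
    ("PI7", 54.1, "prolonged antibiotic courses (%)"),
    ("PI8", 0.0, "same-day NSAID co-prescription (%)"),
    ("PI2", 0.35, "female UTI first-choice/quinolone ratio"),
    ("PI9", 92.0, "flu vaccine coverage (%)"),
    ("PI4", 20.0, "cold/hot seasonal excess (%)"),
]

for pi_id, value, label in probes:
    t = targets[pi_id]
    iv = IndicatorValue(pi_id, "demo", value, 0, 1)
    cls = classify_compliance(iv, t)
    bands = []
    if t.optimal:
        bands.append(f"optimal {t.optimal.op}{t.optimal.value:g}")
    if t.acceptable:
        bands.append(f"acceptable {t.acceptable.op}{t.acceptable.value:g}")
    print(f"{pi_id} = {value:>6}  ({label})")
    print(f"      target: {', '.join(bands)}  ->  {cls.value}")

print("""
Note the boundary semantics: PI4 at exactly 20.0 fails the strict '<20%'
target, while PI9 at 92.0 meets its inclusive '>=90%' target. A value of
exactly 0 is required for the 'optimal 0' targets (PI1, PI3, PI8).""")
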