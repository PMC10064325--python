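# DDD reference keyed by 7-character ATC code.
# ddd_grams: defined daily dose (grams); unit_strength_grams: mass per
# dispensed unit; units_per_package: fallback package content when the claim
# row does not carry one.  Illustrative defaults for the drugs the indicators
# name -- replace with a curated national table for production use.
J01CA04:              # amoxicillin
  ddd_grams: 1.5
  unit_strength_grams: 1.0
  units_per_package: 14
J01CR02:              # amoxicillin/clavulanate (amoxicillin component)
  ddd_grams: 1.5
  unit_strength_grams: 1.0
  units_per_package: 14
J01CA08:              # pivmecillinam
  ddd_grams: 0.8
  unit_strength_grams: 0.4
  units_per_package: 15
J01DC02:              # cefuroxime
  ddd_grams: 0.5
  unit_strength_grams: 0.25
  units_per_package: 10
J01DD13:              # cefpodoxime
  ddd_grams: 0.4
  unit_strength_grams: 0.1
  units_per_package: 10
J01MA01:              # ofloxacin
  ddd_grams: 0.4
  unit_strength_grams: 0.2
  units_per_package: 10
J01MA02:              # ciprofloxacin
  ddd_grams: 1.0
  unit_strength_grams: 0.5
  units_per_package: 10
J01FA06:              # roxithromycin
  ddd_grams: 0.3
  unit_strength_grams: 0.15
  units_per_package: 10
J01FA09:              # clarithromycin
  ddd_grams: 0.5
  unit_strength_grams: 0.25
  units_per_package: 14
J01FG01:              # pristinamycin
  ddd_grams: 2.0
  unit_strength_grams: 0.5
  units_per_package: 16
J01XE01:              # nitrofurantoin
  ddd_grams: 0.2
  unit_strength_grams: 0.05
  units_per_package: 21
J01XX01:              # fosfomycin trometamol
  ddd_grams: 3.0
  unit_strength_grams: 3.0
  units_per_package: 1
J01EE01:              # sulfamethoxazole/trimethoprim (forte tablet)
  ddd_grams: 1.92
  unit_strength_grams: 0.96
  units_per_package: 10
J01AA02:              # doxycycline
  ddd_grams: 0.1
  unit_strength_grams: 0.1
  units_per_package: 15
M01AE01:              # ibuprofen
  ddd_grams: 1.2
  unit_strength_grams: 0.4
  units_per_package: 20
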