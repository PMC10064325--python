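# Pack reference for package-based duration estimation, keyed by ATC code.
# units_per_package: package content (fallback when the claim lacks one);
# units_per_day: assumed posology.  Illustrative defaults -- the estimated
# duration is n_packages x units_per_package / units_per_day.
J01CA04: {units_per_package: 14, units_per_day: 2}   # amoxicillin
J01CR02: {units_per_package: 14, units_per_day: 2}   # amoxicillin/clavulanate
J01CA08: {units_per_package: 15, units_per_day: 3}   # pivmecillinam
J01DC02: {units_per_package: 10, units_per_day: 2}   # cefuroxime
J01DD13: {units_per_package: 10, units_per_day: 2}   # cefpodoxime
J01MA01: {units_per_package: 10, units_per_day: 2}   # ofloxacin
J01MA02: {units_per_package: 10, units_per_day: 2}   # ciprofloxacin
J01FA06: {units_per_package: 10, units_per_day: 2}   # roxithromycin
J01FA09: {units_per_package: 14, units_per_day: 2}   # clarithromycin
J01FG01: {units_per_package: 16, units_per_day: 4}   # pristinamycin
J01XE01: {units_per_package: 21, units_per_day: 3}   # nitrofurantoin
J01XX01: {units_per_package: 1, units_per_day: 1}    # fosfomycin trometamol
J01EE01: {units_per_package: 10, units_per_day: 2}   # sulfamethoxazole/trimethoprim
J01AA02: {units_per_package: 15, units_per_day: 1}   # doxycycline
M01AE01: {units_per_package: 20, units_per_day: 3}   # ibuprofen
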