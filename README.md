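# abxstew

Antibiotic-use surveillance indicators for nursing homes, computed from
pharmacy-claims extracts.

Nursing-home residents are among the most antibiotic-exposed populations in
high-income countries, yet most facilities have no on-site pharmacy and no
clinical database to audit — what exists at scale is reimbursement claims:
who was dispensed which drug (ATC code), when, by which route, and how many
packages. `abxstew` turns such claims into the consensus surveillance set
used for antimicrobial-stewardship monitoring in nursing homes:

* **14 quantity metrics (QM1–QM14)** — volume of use: dispensings and WHO
  defined daily doses (DDDs) per 100 resident-days overall and for
  amoxicillin/clavulanate, cephalosporins, quinolones and MLSK; the share
  of residents on antibiotics; the parenteral route share; urine-culture
  rates.
* **10 proxy indicators (PI1–PI10)** — appropriateness estimated from
  claims alone, each classified against its consensus target: drug choice
  in the week after a urine culture (by sex), repeat quinolone courses
  within 6 months, cold-vs-hot-season excess, first-line/second-line
  ratio, prolonged courses (estimated duration >7 days from package
  counts), same-day NSAID co-prescription, flu-vaccine coverage, and the
  oral share of cephalosporins.

For a facility-year, a rate indicator is `scale x numerator / denominator`
— e.g. QM1 = 100 x (J01 dispensings) / (resident-days), and PI7 =
100 x (dispensings of eight monitored drugs with estimated duration
> 7 days) / (all dispensings of those drugs), where duration is estimated
as `packages x units/package / units-per-day` because claims do not record
prescription length. Facility values are benchmarked as regional medians
and IQRs, and each proxy indicator is classified optimal / acceptable /
non-compliant against bands such as "optimal <5%, acceptable <20%".

Because the national claims databases this is designed for are not
redistributable, the package includes a synthetic-claims generator
(`abxstew.simulate`) with configurable rates, seasonal forcing, class
mixtures and event linkage — and closed-form expected indicator values —
so the whole pipeline is testable end to end.

## Worked example

`examples/01_compute_indicators.py` builds a six-resident facility (1369
resident-days in 2019, 13 antibiotic dispensings, four urine cultures,
four flu vaccines plus one look-back quinolone) and prints all 24
indicators:

```
  QM1:   0.9496   (num 13 / den 1369)
  QM3:  83.3333   (num 5 / den 6)
 QM12:   8.3333   (num 1 / den 12)
  ...
  PI3:  50.0000   (num 1 / den 2)   [non_compliant]
  PI5:   0.0000   (num 1 / den 1)   [optimal]
  PI7:  30.0000   (num 3 / den 10)   [non_compliant]
  PI9:  80.0000   (num 4 / den 5)   [non_compliant]
```

Reading it: the facility dispensed 0.95 antibiotic prescriptions per 100
resident-days (QM1); 83% of residents received at least one antibiotic
(QM3); 8.3% of route-known antibiotic dispensings were parenteral (QM12).
Half of the year's quinolone dispensings followed another quinolone within
6 months (PI3 = 50, far above the acceptable <10% band, hence
non-compliant), while amoxicillin/clavulanate use was seasonally balanced
(PI5 = 0, optimal under "<20%").

The other examples cover simulation plus regional benchmarking
(`02_simulate_and_benchmark.py`), target classification semantics
(`03_compliance_targets.py`) and DDD/duration arithmetic
(`04_ddd_and_duration.py`).

## Command line

A thin CLI wraps the library:

```sh
abxstew simulate --seed 7 --out claims/            # synthetic dataset + truth.csv
abxstew compute --dispensings claims/dispensings.csv --stays claims/stays.csv \
    --events claims/events.csv --year 2019 --out results/
abxstew summarize --indicators results/facility_indicators.csv --out results/
```

`compute` validates the input (failing on duplicate ids, overlapping stays
or malformed rows), computes all 24 indicators per facility, and writes
`facility_indicators.csv`, `regional_summary.csv` (median/IQR per
indicator) and per-facility feedback reports. `--dedupe`, `--uc-window`,
`--lookback-days` and `--date-format` expose the documented conventions.

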