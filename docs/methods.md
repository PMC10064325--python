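# Methods

`abxstew` computes a consensus surveillance set of 24 antibiotic-use
indicators for nursing homes from pharmacy-reimbursement claims: 14
quantity metrics (QMs) describing the volume of dispensing, and 10 proxy
indicators (PIs) estimating the appropriateness of prescribing without any
clinical data, each with a consensus compliance target. This note records
the computational model, the conventions the engine pins down where the
indicator definitions leave room, the synthetic-data model, and the known
limitations.

## Data model and assumptions

The input is three flat tables: dispensing records (resident, facility,
date, ATC code, route, number of packages), resident stays (entry/exit,
sex, birth year) and clinical events (urine cultures, flu vaccines).
This mirrors what claims databases actually contain: drug, quantity and
date are reliable; indication and prescribed duration are absent.

Core assumptions:

* **One dispensing row = one "prescription".** Claims do not distinguish
  multi-drug prescriptions, so each reimbursed drug row is the counting
  unit everywhere. Repeat same-day same-drug rows count separately by
  default (they occur legitimately in claims extracts); a `dedupe` option
  collapses them when an extract is known to contain technical duplicates.
* **Resident-days are counted inclusively** over calendar days: a same-day
  entry and exit contributes one day; open-ended stays are truncated at the
  analysis-period end. The analysis period is one calendar year.
* **`unknown` is an explicit value** for route, sex and package content,
  never imputed. Route-share indicators (QM12, PI10) exclude route-unknown
  records from both numerator and denominator, so a facility with poor
  route coding is not biased toward either end; the exclusion count is
  carried as a data-quality flag.
* Rate metrics are scaled per 100 resident-days; share metrics (QM3, QM12,
  QM14) and percentage PIs are on a 0–100 scale, matching the magnitudes
  on which the consensus targets are expressed.

## Drug classes and reference tables

Class membership is ATC-prefix matching: J01 (all systemic
antibacterials), J01CR02 (amoxicillin/clavulanate), J01D (cephalosporins),
J01M (quinolones), J01F (MLSK), J01CA04 (amoxicillin), J01XE01
(nitrofurantoin), J01XX01 (fosfomycin trometamol), J01CA08
(pivmecillinam), J01EE01 (sulfamethoxazole/trimethoprim), M01A (systemic
NSAIDs), J07BB (influenza vaccines). The prolonged-course indicator is
restricted to eight named drugs; the package maps the names to ATC codes
J01CA04, J01CR02, J01DC02 (cefuroxime), J01DD13 (cefpodoxime), J01FA06
(roxithromycin), J01FA09 (clarithromycin), J01FG01 (pristinamycin) and
J01XE01 (nitrofurantoin).

Two editable YAML references are shipped:

* **DDD reference** — per 7-character ATC code: WHO defined daily dose
  (grams), strength per dispensed unit, fallback package content. DDDs per
  dispensing = packages x units/package x unit strength / DDD.
* **Pack reference** — package content and an assumed posology
  (units/day). Estimated course duration = packages x units/package /
  units/day. Units per package come from the claim row when present.

The shipped values are plausible defaults for the French market (e.g.
amoxicillin 1 g x 14 tablets at 2/day), chosen so that one package of each
monitored drug lasts at most 7 days and two packages more than 7. They are
deliberately *illustrative*: the engine is value-agnostic and production
use should substitute a curated national table. How many units per day a
prescription implies is an assumption of this package, not a recorded
fact.

## Indicator conventions

Decisions taken where the printed calculation descriptions leave latitude:

* **UC linkage (PI1/PI2).** A dispensing is linked to a urine culture when
  the same resident has a culture dated 0–7 days (inclusive) before the
  dispensing; day 0 counts because same-day treatment after sampling is the
  common clinical pattern. The window applies to *both* the numerator and
  the denominator class sets ("in the week following UC" reads on the whole
  ratio). The window length is configurable.
* **Repeat quinolones (PI3).** "Preceding 6 months" = 1–180 days strictly
  before the index dispensing. The look-back may cross into the prior
  calendar year, so the engine accepts (and the simulator emits) a
  look-back extract; a dataset with no pre-year dispensings gets a
  completeness flag on PI3 rather than a silently low value.
* **Seasons.** Cold season is January–March plus October–December of the
  analysis year; hot season April–September. Seasonal variation is
  (cold/hot − 1) x 100 and is undefined when the hot-season count is zero.
* **Prolonged courses (PI7).** Strictly greater than 7.0 estimated days; a
  7.0-day course is not prolonged. The threshold follows the consensus
  revision of the cut-off from >8 to >7 days.
* **Flu coverage (PI9).** The numerator counts vaccine *dispensings* in the
  cold season (events, or J07BB dispensing rows), matching the printed
  wording; repeat doses can push the value above 100, which is flagged, not
  capped. The denominator is residents with at least one cold-season
  stay-day (no minimum stay).
* **Zero denominators.** Every ratio with a zero (or below-threshold)
  denominator is *undefined*, flagged, and excluded from regional medians —
  never coerced to 0 or infinity, which would distort benchmarking given
  how dispersed small-facility ratios are.
* **Compliance classification.** Targets are encoded as ordered bounds with
  the printed strictness: e.g. prolonged courses optimal `<5`, acceptable
  `<20`; seasonal variation `<20` (so exactly 20.0 is non-compliant); flu
  coverage `>=90`; "optimal 0" means exactly zero. Undefined values
  classify as undefined.

## Aggregation and reporting

Regional summaries are the median and quartiles of each indicator across
facilities, over defined values only; undefined values are reported as
counts. Quartiles use linear interpolation between order statistics — the
convention is pinned because IQRs are otherwise not reproducible across
implementations. A configurable minimum number of facilities (pipeline
default 2) suppresses summaries of nearly-empty regions; the
`summarize_region` function itself summarizes any non-empty input.
Facility feedback reports show one facility's values against the anonymous
regional distribution (median, IQR, midrank percentile) plus compliance
classes, without exposing other facilities' identities.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical outputs.

## Synthetic claims model

The real input to this kind of surveillance is a national reimbursement
database that cannot be redistributed, so the package ships a generator
that emulates its structure with known ground truth:

* Facility sizes are Gaussian (mean 92, SD 34 by default, matching
  published 2019 facility profiles); residents are 75% female, mean age
  87.5; a configurable fraction of stays turn over during the year.
* Antibiotic dispensings are a per-resident Poisson process at `abx_rate`
  per 100 resident-days (default 0.52), thinned seasonally: the cold-season
  daily rate is `m` times the hot-season rate (default m = 1.35) with the
  annual mean held at `abx_rate`. Dates are uniform within season blocks,
  which is sufficient at the month-level granularity the indicators use.
* Drug class, concrete ATC code, route (per-class parenteral share) and
  package count are drawn from stated mixtures. Default class shares put
  the class-specific rates near published regional medians given the
  default `abx_rate`.
* Urine cultures are Poisson (`uc_rate`, default 0.15/100 resident-days);
  each triggers a UC-linked dispensing 0–7 days later with probability
  `p_abx_given_uc`, drawn from a sex-specific drug mixture; those inserted
  records are tagged so the generator carries its own ground truth for the
  window-linked ratios instead of a fragile analytic approximation.
* Quinolone dispensings spawn a repeat within 7–150 days with
  `repeat_fq_prob`; each in-year antibiotic dispensing gets a same-day
  NSAID with `nsaid_coprescription_prob`; each resident present in the
  cold season receives one flu vaccine with `flu_coverage_prob`
  (default 0.81).
* The final 180 days of the prior year are emitted as a look-back extract.

`expected_indicators` returns the closed-form expectations these
parameters imply for the base process: QM1 = `abx_rate`; class-count QMs =
`abx_rate` x class probability; QM12 = mixture-weighted parenteral share;
PI4/PI5 = (m − 1) x 100 (ignoring the one-day cold/hot length difference);
PI6 = first-line over second-line mixture mass; PI7 = P(two packages) x 100
under the shipped pack reference; PI8 and PI9 = their probabilities x 100.
These hold exactly when the UC-insertion and repeat channels are off and
stays are full-year; with the channels on they are base-process values
that the realized rates exceed by the insertion rates. The parameter
-recovery tests therefore run with those channels off and zero turnover —
isolating the channel being measured, at 20 seeds of 10 facilities x 50
residents (and a reduced 10-seed version in the acceptance script), sizes
chosen to give Monte-Carlo standard errors small enough to detect
mis-specification while keeping the suite fast. No closed form is provided
for PI3 (it depends on within-year course clustering); it is verified with
hand-built fixtures instead.

What the generator does **not** emulate: prescriber behaviour and
facility-level practice heterogeneity beyond Poisson noise (real
between-facility IQRs are wider), antimicrobial resistance dynamics,
dose adjustments, hospital-dispensed drugs, and any calibration to real
microdata. Passing tests therefore demonstrate that the engine measures
what the definitions say on data of the right *shape and scale* — not that
real-world medians will match.

## Numerical and degenerate-input choices

* Duplicate record ids and overlapping stays are validation errors (the
  pipeline refuses by default); dispensings or events outside every
  recorded stay, and residents without stay records, are warnings.
* Residents appearing in the QM3/QM14 numerator without a stay record are
  dropped from the numerator (with a flag) so the shares stay in [0, 100].
* Malformed rows (bad date, bad ATC, non-positive quantities) are excluded
  and itemized in the validation report; no input row is dropped silently.
* Reference tables reject non-positive strengths, DDDs or posologies at
  load time.
* Ratio indicators carry their numerator and denominator so any value can
  be audited and region-pooled exactly.

## Limitations

* Package-based duration estimation cannot see dose tapering, splitting a
  box across two courses, or stockpiling; PI7 is a proxy by construction.
* Without a look-back extract PI3 undercounts repeats; the flag makes this
  visible but cannot correct it.
* Crude rates only: no age, sex or case-mix adjustment (the consensus set
  is defined on crude rates).
* The shipped DDD/pack values are defaults, not a versioned WHO release;
  DDD-based metrics (QM2/5/7/9/11) are only as good as the supplied table.
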