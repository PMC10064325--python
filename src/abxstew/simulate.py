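"""Synthetic nursing-home claims generator with known ground truth.

The national reimbursement database the indicators were designed for is not
publicly available, so this module generates claims datasets with the same
structure — per-resident dispensing streams with ATC codes, dates, routes
and package counts, linked to stays and urine-culture dates — from an
explicit stochastic model whose parameters map directly onto the
indicators:

* dispensings are a per-resident Poisson process at ``abx_rate`` per 100
  resident-days, thinned seasonally (cold-season rate is
  ``seasonal_multiplier`` times the hot-season rate, with the overall rate
  held at ``abx_rate``);
* drug class, route and package count are drawn from stated mixtures;
* urine cultures are Poisson; each triggers, with probability
  ``p_abx_given_uc``, a UC-linked dispensing 0-7 days later drawn from a
  sex-specific drug mixture;
* quinolone courses repeat within 180 days with ``repeat_fq_prob``;
  NSAIDs are co-dated with ``nsaid_coprescription_prob``; one flu vaccine
  per resident in the cold season with ``flu_coverage_prob``;
* the final 180 days of the prior year are emitted as a look-back extract.

:func:`expected_indicators` returns the closed-form expectations the
parameters imply for the base process, which is what makes every indicator
testable end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np

from .atc import load_default_ddd_reference, load_default_pack_reference
from .claims import (
    ClaimsDataset,
    ClinicalEvent,
    DispensingRecord,
    EventType,
    ResidentStay,
    Route,
    Sex,
)
from .qm import cold_periods, hot_period, year_period

__all__ = ["SimulationParams", "GroundTruth", "generate_dataset", "expected_indicators"]


# Concrete ATC codes drawn within each mixture class (code, weight).
CLASS_CODES: Mapping[str, tuple] = {
    "AMOX": (("J01CA04", 1.0),),
    "AMC": (("J01CR02", 1.0),),
    "CEPH": (("J01DC02", 0.5), ("J01DD13", 0.5)),
    "FQ": (("J01MA01", 0.5), ("J01MA02", 0.5)),
    "MLSK": (("J01FA09", 0.5), ("J01FA06", 0.3), ("J01FG01", 0.2)),
    "OTHER": (("J01AA02", 0.7), ("J01EE01", 0.3)),
}

_PARENTERAL_ROUTES = (Route.IV, Route.IM, Route.SC)
_PARENTERAL_WEIGHTS = (0.5, 0.3, 0.2)


def _default_class_mixture() -> dict:
    # Class shares chosen so class-specific rates sit near French 2019
    # regional medians given abx_rate ~0.52/100 resident-days.
    return {"AMOX": 0.20, "AMC": 0.18, "CEPH": 0.14, "FQ": 0.07,
            "MLSK": 0.10, "OTHER": 0.31}


def _default_parenteral_share() -> dict:
    # Overall parenteral share ~9%; cephalosporins are the main
    # parenteral-capable class in this setting.
    return {"default": 0.06, "CEPH": 0.30}


def _default_post_uc_male() -> dict:
    return {"J01CA04": 0.25, "J01CR02": 0.20, "J01XE01": 0.15, "J01XX01": 0.10,
            "J01CA08": 0.05, "J01MA01": 0.10, "J01MA02": 0.05, "J01DD13": 0.05,
            "J01EE01": 0.05}


def _default_post_uc_female() -> dict:
    return {"J01XE01": 0.30, "J01XX01": 0.25, "J01CA08": 0.05, "J01CA04": 0.15,
            "J01CR02": 0.10, "J01MA01": 0.10, "J01MA02": 0.05}


@dataclass
class SimulationParams:
    """Study-condition parameters of the generator ("france-2019-like").

    Defaults emulate the published 2019 facility profile (about 92
    residents per facility, 75% women, mean age ~87.5 years) and sit near
    the printed regional medians for the rates they control (e.g.
    ``abx_rate`` 0.52 dispensings/100 resident-days, flu coverage 0.81);
    they are illustrative conditions, not a reproduction claim.
    """

    year: int = 2019
    n_facilities: int = 20
    residents_per_facility: float = 92.0
    residents_dispersion: float = 34.0     # SD of facility size
    sex_ratio_female: float = 0.75
    mean_age: float = 87.5
    sd_age: float = 7.0
    turnover_rate: float = 0.25            # fraction with partial-year stays
    abx_rate: float = 0.52                 # J01 dispensings / 100 resident-days
    class_mixture: dict = field(default_factory=_default_class_mixture)
    parenteral_share: dict = field(default_factory=_default_parenteral_share)
    seasonal_multiplier: float = 1.35      # cold-season rate inflation
    p_two_packages: float = 0.5            # else one package per dispensing
    uc_rate: float = 0.15                  # urine cultures / 100 resident-days
    p_abx_given_uc: float = 0.5
    post_uc_mixture_male: dict = field(default_factory=_default_post_uc_male)
    post_uc_mixture_female: dict = field(default_factory=_default_post_uc_female)
    uc_window_days: int = 7
    repeat_fq_prob: float = 0.25
    nsaid_coprescription_prob: float = 0.02
    flu_coverage_prob: float = 0.81
    lookback_days: int = 180
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "sex_ratio_female": self.sex_ratio_female,
            "turnover_rate": self.turnover_rate,
            "p_two_packages": self.p_two_packages,
            "p_abx_given_uc": self.p_abx_given_uc,
            "repeat_fq_prob": self.repeat_fq_prob,
            "nsaid_coprescription_prob": self.nsaid_coprescription_prob,
            "flu_coverage_prob": self.flu_coverage_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name, rate in (("abx_rate", self.abx_rate), ("uc_rate", self.uc_rate)):
            if rate < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seasonal_multiplier <= 0:
            raise ValueError("seasonal_multiplier must be > 0")
        if self.n_facilities < 1 or self.residents_per_facility < 1:
            raise ValueError("need at least one facility and one resident")
        for name, mix in (("class_mixture", self.class_mixture),
                          ("post_uc_mixture_male", self.post_uc_mixture_male),
                          ("post_uc_mixture_female", self.post_uc_mixture_female)):
            if mix and not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has a negative weight")
        unknown = set(self.class_mixture) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown class_mixture keys: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Expectations implied by the generator parameters.

    ``expected`` maps indicator id -> closed-form expectation of the base
    process (None where no closed form is provided); ``notes`` documents
    each derivation; ``uc_tagged`` carries, per facility, the numerator and
    denominator counts of the *inserted* UC-linked dispensings for PI1/PI2,
    which is the generator's own ground truth for the window-linked ratios.
    """

    expected: dict
    notes: dict
    uc_tagged: dict = field(default_factory=dict)


def _season_day_counts(year: int) -> tuple:
    cold = sum(p.n_days for p in cold_periods(year))
    hot = hot_period(year).n_days
    return cold, hot


def _hot_day_rate(params: SimulationParams) -> float:
    """Per-day hot-season dispensing hazard holding the annual mean at abx_rate."""
    c, h = _season_day_counts(params.year)
    return (params.abx_rate / 100.0) * (c + h) / (params.seasonal_multiplier * c + h)


def expected_indicators(params: SimulationParams) -> GroundTruth:
    """Closed-form base-process expectations for the generator parameters.

    Derivations assume full-year stays and hold exactly when the
    UC-insertion and quinolone-repeat channels are off (those channels add
    dispensings on top of the base Poisson process); with them on, the
    rate expectations are lower bounds and the mixture ratios approximate.
    QM3 and QM14 use the Poisson zero-class probability and are
    asymptotic in facility size.
    """
    params.validate()
    mix = params.class_mixture
    c, h = _season_day_counts(params.year)
    m = params.seasonal_multiplier
    year_days = c + h
    annual_lambda = params.abx_rate / 100.0 * year_days
    uc_lambda = params.uc_rate / 100.0 * year_days

    par_share = sum(
        p * params.parenteral_share.get(cls, params.parenteral_share.get("default", 0.0))
        for cls, p in mix.items())

    ddd_ref = load_default_ddd_reference()
    mean_packs = 1.0 + params.p_two_packages
    mean_ddd = 0.0
    for cls, p_cls in mix.items():
        for code, w in CLASS_CODES[cls]:
            e = ddd_ref[code]
            mean_ddd += p_cls * w * e.units_per_package * e.unit_strength_grams / e.ddd_grams
    mean_ddd *= mean_packs

    pack_ref = load_default_pack_reference()
    # PI7 closed form needs every monitored drug to cross the 7-day line
    # exactly between one and two packages under the shipped pack reference.
    from .atc import PI7_DRUG_CODES
    split_ok = all(
        pack_ref[code].units_per_package / pack_ref[code].units_per_day <= 7.0
        < 2 * pack_ref[code].units_per_package / pack_ref[code].units_per_day
        for code in PI7_DRUG_CODES)

    def mix_sum(mixture: Mapping, codes: tuple) -> float:
        return sum(p for code, p in mixture.items() if any(code.startswith(c) for c in codes))

    pi1_num = mix_sum(params.post_uc_mixture_male,
                      ("J01XE01", "J01XX01", "J01CA08", "J01CA04", "J01CR02"))
    pi1_den = mix_sum(params.post_uc_mixture_male, ("J01M", "J01D", "J01EE01"))
    pi2_num = mix_sum(params.post_uc_mixture_female, ("J01XE01", "J01XX01", "J01CA08"))
    pi2_den = mix_sum(params.post_uc_mixture_female, ("J01M",))

    second_line = mix["FQ"] + mix["CEPH"] + mix["MLSK"]
    expected = {
        "QM1": params.abx_rate,
        "QM2": params.abx_rate * mean_ddd,
        "QM3": 100.0 * (1.0 - math.exp(-annual_lambda)),
        "QM4": params.abx_rate * mix["AMC"],
        "QM5": None,
        "QM6": params.abx_rate * mix["CEPH"],
        "QM7": None,
        "QM8": params.abx_rate * mix["FQ"],
        "QM9": None,
        "QM10": params.abx_rate * mix["MLSK"],
        "QM11": None,
        "QM12": 100.0 * par_share,
        "QM13": params.uc_rate,
        "QM14": 100.0 * (1.0 - math.exp(-uc_lambda)),
        "PI1": pi1_num / pi1_den if pi1_den > 0 else None,
        "PI2": pi2_num / pi2_den if pi2_den > 0 else None,
        "PI3": None,
        "PI4": (m - 1.0) * 100.0,
        "PI5": (m - 1.0) * 100.0,
        "PI6": (mix["AMOX"] + mix["AMC"]) / second_line if second_line > 0 else None,
        "PI7": 100.0 * params.p_two_packages if split_ok else None,
        "PI8": 100.0 * params.nsaid_coprescription_prob,
        "PI9": 100.0 * params.flu_coverage_prob,
        "PI10": 100.0 * (1.0 - params.parenteral_share.get(
            "CEPH", params.parenteral_share.get("default", 0.0))),
    }
    notes = {
        "QM1": "base Poisson rate: abx_rate per 100 resident-days",
        "QM2": "abx_rate x mean DDDs per dispensing under the class mixture, "
               "code weights and package distribution",
        "QM3": "100 x (1 - exp(-annual per-resident rate)); full-year stays",
        "QM4": "abx_rate x class probability (AMC)",
        "QM6": "abx_rate x class probability (CEPH)",
        "QM8": "abx_rate x class probability (FQ)",
        "QM10": "abx_rate x class probability (MLSK)",
        "QM12": "mixture-weighted parenteral route share x 100",
        "QM13": "base Poisson rate: uc_rate per 100 resident-days",
        "QM14": "100 x (1 - exp(-annual urine-culture rate)); full-year stays",
        "PI1": "ratio of post-UC male mixture mass: first-choice / reserve classes",
        "PI2": "ratio of post-UC female mixture mass: first-choice / quinolones",
        "PI3": "no closed form provided (depends on within-year course clustering "
               "and the look-back); checked via hand-built fixtures instead",
        "PI4": "(m - 1) x 100 from the seasonal thinning; ignores the one-day "
               "difference between cold (182) and hot (183) season lengths",
        "PI5": "identical to PI4: seasonal thinning is class-independent",
        "PI6": "(p_AMOX + p_AMC) / (p_FQ + p_CEPH + p_MLSK)",
        "PI7": "P(two packages) x 100: under the shipped pack reference one "
               "package of every monitored drug lasts <=7 days and two packages >7",
        "PI8": "nsaid_coprescription_prob x 100 (each J01 dispensing iid)",
        "PI9": "flu_coverage_prob x 100 (one vaccine per covered resident)",
        "PI10": "100 x (1 - parenteral share of cephalosporins)",
    }
    return GroundTruth(expected=expected, notes=notes)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, items: tuple):
    codes = [c for c, _ in items]
    weights = np.array([w for _, w in items], dtype=float)
    return codes[rng.choice(len(codes), p=weights / weights.sum())]


def _pick_from_mixture(rng: np.random.Generator, mixture: Mapping):
    keys = sorted(mixture)
    probs = np.array([mixture[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_dataset(params: SimulationParams,
                     seed: Optional[int] = None) -> tuple:
    """Generate a claims dataset and its ground truth; fully seed-reproducible.

    Returns ``(ClaimsDataset, GroundTruth)``.  The dataset includes a
    look-back extract (dispensings from the final ``lookback_days`` of the
    prior year) so the repeat-quinolone indicator can see prior courses.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    year = params.year
    period = year_period(year)
    lb_start = period.start - timedelta(days=params.lookback_days)

    # day grid over look-back + analysis year, split cold/hot by month
    all_days = np.array([lb_start + timedelta(days=i)
                         for i in range((period.end - lb_start).days + 1)])
    day_ordinals = np.array([d.toordinal() for d in all_days])
    cold_mask = np.array([d.month in (1, 2, 3, 10, 11, 12) for d in all_days])
    year_mask = day_ordinals >= period.start.toordinal()

    r_hot = _hot_day_rate(params)
    r_cold = r_hot * params.seasonal_multiplier
    uc_day_rate = params.uc_rate / 100.0

    pack_ref = load_default_pack_reference()
    class_names = sorted(params.class_mixture)
    class_probs = np.array([params.class_mixture[c] for c in class_names], dtype=float)
    class_probs = class_probs / class_probs.sum()

    dispensings: list = []
    stays: list = []
    events: list = []
    uc_tagged: dict = {}
    rec_counter = 0

    def next_id() -> str:
        nonlocal rec_counter
        rec_counter += 1
        return f"d{rec_counter:07d}"

    def make_dispensing(resident_id, facility_id, when: date, atc: str,
                        route: Route) -> DispensingRecord:
        n_packages = 2 if rng.random() < params.p_two_packages else 1
        upp = pack_ref[atc].units_per_package if atc in pack_ref else None
        return DispensingRecord(
            record_id=next_id(), resident_id=resident_id, facility_id=facility_id,
            dispense_date=when, atc_code=atc, route=route,
            n_packages=n_packages, units_per_package=upp,
            prescriber_id=f"gp{rng.integers(1, 500):04d}")

    def draw_route(cls: str) -> Route:
        share = params.parenteral_share.get(
            cls, params.parenteral_share.get("default", 0.0))
        if rng.random() < share:
            return _PARENTERAL_ROUTES[rng.choice(3, p=np.array(_PARENTERAL_WEIGHTS))]
        return Route.ORAL

    for fi in range(params.n_facilities):
        facility_id = f"nh{fi + 1:03d}"
        tagged = {"PI1": [0, 0], "PI2": [0, 0]}
        uc_tagged[facility_id] = tagged
        n_res = max(1, int(round(rng.normal(params.residents_per_facility,
                                            params.residents_dispersion))))
        for ri in range(n_res):
            resident_id = f"{facility_id}-r{ri + 1:04d}"
            sex = Sex.FEMALE if rng.random() < params.sex_ratio_female else Sex.MALE
            birth_year = year - int(round(rng.normal(params.mean_age, params.sd_age)))

            if rng.random() < params.turnover_rate:
                if rng.random() < 0.5:  # admitted during the year
                    entry = period.start + timedelta(days=int(rng.integers(0, 365)))
                    exit_d: Optional[date] = None
                else:                   # left during the year
                    entry = period.start - timedelta(days=int(rng.integers(30, 720)))
                    exit_d = period.start + timedelta(days=int(rng.integers(0, 365)))
            else:
                entry = period.start - timedelta(days=int(rng.integers(30, 720)))
                exit_d = None
            stays.append(ResidentStay(resident_id, facility_id, entry, exit_d,
                                      sex, birth_year))

            lo = max(entry.toordinal(), lb_start.toordinal())
            hi = (exit_d or period.end).toordinal()
            present = (day_ordinals >= lo) & (day_ordinals <= hi)
            cold_days = all_days[present & cold_mask]
            hot_days = all_days[present & ~cold_mask]
            year_days = all_days[present & year_mask]

            # base antibiotic process, seasonally thinned
            for pool, rate in ((cold_days, r_cold), (hot_days, r_hot)):
                if pool.size == 0 or rate == 0:
                    continue
                for idx in rng.integers(0, pool.size, rng.poisson(rate * pool.size)):
                    cls = class_names[rng.choice(len(class_names), p=class_probs)]
                    atc = _weighted_choice(rng, CLASS_CODES[cls])
                    dispensings.append(make_dispensing(
                        resident_id, facility_id, pool[idx], atc, draw_route(cls)))

            # urine cultures and UC-linked prescribing
            if year_days.size:
                n_uc = rng.poisson(uc_day_rate * year_days.size)
                for idx in rng.integers(0, year_days.size, n_uc):
                    uc_date = year_days[idx]
                    events.append(ClinicalEvent(resident_id, facility_id, uc_date,
                                                EventType.URINE_CULTURE))
                    if rng.random() < params.p_abx_given_uc:
                        delay = int(rng.integers(0, params.uc_window_days + 1))
                        when = min(uc_date + timedelta(days=delay), period.end)
                        mixture = (params.post_uc_mixture_male if sex is Sex.MALE
                                   else params.post_uc_mixture_female)
                        atc = _pick_from_mixture(rng, mixture)
                        dispensings.append(make_dispensing(
                            resident_id, facility_id, when, atc, Route.ORAL))
                        pi_id = "PI1" if sex is Sex.MALE else "PI2"
                        num_codes = (("J01XE01", "J01XX01", "J01CA08", "J01CA04", "J01CR02")
                                     if sex is Sex.MALE
                                     else ("J01XE01", "J01XX01", "J01CA08"))
                        den_codes = (("J01M", "J01D", "J01EE01") if sex is Sex.MALE
                                     else ("J01M",))
                        if any(atc.startswith(c) for c in num_codes):
                            tagged[pi_id][0] += 1
                        elif any(atc.startswith(c) for c in den_codes):
                            tagged[pi_id][1] += 1

            # flu vaccination in the cold season
            year_cold = all_days[present & year_mask & cold_mask]
            if year_cold.size and rng.random() < params.flu_coverage_prob:
                events.append(ClinicalEvent(
                    resident_id, facility_id,
                    year_cold[rng.integers(0, year_cold.size)], EventType.FLU_VACCINE))

    # repeat quinolone courses within the look-back window
    repeats = []
    for rec in dispensings:
        if rec.atc_code.startswith("J01M") and rng.random() < params.repeat_fq_prob:
            gap = int(rng.integers(7, 151))
            when = rec.dispense_date + timedelta(days=gap)
            if when <= period.end:
                repeats.append(make_dispensing(rec.resident_id, rec.facility_id,
                                               when, rec.atc_code, Route.ORAL))
    dispensings.extend(repeats)

    # same-day NSAID co-dispensings
    nsaids = []
    for rec in dispensings:
        if (rec.atc_code.startswith("J01") and period.contains(rec.dispense_date)
                and rng.random() < params.nsaid_coprescription_prob):
            nsaids.append(make_dispensing(rec.resident_id, rec.facility_id,
                                          rec.dispense_date, "M01AE01", Route.ORAL))
    dispensings.extend(nsaids)

    dataset = ClaimsDataset(dispensings, stays, events, analysis_year=year)
    truth = expected_indicators(params)
    truth.uc_tagged = uc_tagged
    return dataset, truth
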