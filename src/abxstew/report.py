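"""Facility-level indicator sets, regional median/IQR benchmarking, and the
end-to-end pipeline.

Regional summaries are medians and quartiles across facilities, computed
over *defined* values only (undefined values are counted, never coerced to
0 or infinity).  Quartiles use linear interpolation, pinned so the IQR is
reproducible across implementations.  Per-facility feedback reports show a
facility only its own values against the anonymous regional distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atc import DddReference, PackReference
from .claims import ClaimsDataset, CsvDialect, load_dataset
from .pi import (
    DEFAULT_LOOKBACK_DAYS,
    DEFAULT_UC_WINDOW_DAYS,
    PI_IDS,
    PIResult,
    compute_all_pis,
    load_default_targets,
    load_targets_yaml,
)
from .qm import QM_IDS, IndicatorValue, compute_all_qms

logger = logging.getLogger(__name__)

__all__ = [
    "FacilityIndicatorSet",
    "RegionalSummary",
    "PipelineConfig",
    "PipelineError",
    "compute_facility_set",
    "summarize_region",
    "percentile_rank",
    "facility_report",
    "run_pipeline",
]

ALL_INDICATOR_IDS = QM_IDS + PI_IDS


@dataclass(frozen=True)
class FacilityIndicatorSet:
    """The 24 computed indicators for one facility-year."""

    facility_id: str
    year: int
    qms: tuple          # 14 IndicatorValue
    pis: tuple          # 10 PIResult

    def __post_init__(self) -> None:
        if len(self.qms) != 14 or len(self.pis) != 10:
            raise ValueError("a facility set holds exactly 14 QMs and 10 PIs")

    def values(self) -> list:
        """All 24 IndicatorValues, QM1..QM14 then PI1..PI10."""
        return list(self.qms) + [p.value for p in self.pis]

    def compliance(self) -> dict:
        return {p.value.indicator_id: p.compliance for p in self.pis}


@dataclass(frozen=True)
class RegionalSummary:
    """Median and quartiles of one indicator across facilities."""

    indicator_id: str
    n_defined: int
    n_undefined: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    defined_values: tuple = ()

    @property
    def defined(self) -> bool:
        return self.median is not None


def compute_facility_set(dataset: ClaimsDataset, facility_id: str, year: int, *,
                         ddd_ref: Optional[DddReference] = None,
                         pack_ref: Optional[PackReference] = None,
                         targets: Optional[Mapping] = None,
                         uc_window_days: int = DEFAULT_UC_WINDOW_DAYS,
                         lookback_days: int = DEFAULT_LOOKBACK_DAYS,
                         suppression_threshold: float = 0) -> FacilityIndicatorSet:
    qms = compute_all_qms(dataset, facility_id, year, ddd_ref=ddd_ref,
                          suppression_threshold=suppression_threshold)
    pis = compute_all_pis(dataset, facility_id, year, pack_ref=pack_ref,
                          targets=targets, uc_window_days=uc_window_days,
                          lookback_days=lookback_days)
    return FacilityIndicatorSet(facility_id, year, tuple(qms), tuple(pis))


def summarize_region(values: Sequence[IndicatorValue], min_n: int = 1) -> RegionalSummary:
    """Median and IQR over the defined values of one indicator.

    Quartiles use linear interpolation between order statistics.  With
    fewer than *min_n* defined values the summary is undefined but the
    defined/undefined counts are still reported.
    """
    if not values:
        raise ValueError("summarize_region needs at least one IndicatorValue")
    ids = {v.indicator_id for v in values}
    if len(ids) != 1:
        raise ValueError(f"mixed indicator ids in one summary: {sorted(ids)}")
    indicator_id = ids.pop()
    defined = [v.value for v in values if v.value is not None]
    n_undefined = len(values) - len(defined)
    if len(defined) < max(min_n, 1):
        return RegionalSummary(indicator_id, len(defined), n_undefined, None, None, None)
    q1, med, q3 = np.percentile(defined, [25, 50, 75], method="linear")
    return RegionalSummary(indicator_id, len(defined), n_undefined,
                           float(med), float(q1), float(q3), tuple(defined))


def percentile_rank(value: float, population: Sequence[float]) -> float:
    """Midrank percentile of *value* within *population* (0-100 scale)."""
    arr = np.asarray(population, dtype=float)
    if arr.size == 0:
        raise ValueError("empty population")
    less = np.count_nonzero(arr < value)
    equal = np.count_nonzero(arr == value)
    return 100.0 * (less + 0.5 * equal) / arr.size


def facility_report(fset: FacilityIndicatorSet, summaries: Mapping) -> tuple:
    """Per-facility feedback: (DataFrame, human-readable text).

    Each row carries the facility value, regional median/IQR, the
    facility's percentile rank (midrank convention) and, for proxy
    indicators, the compliance class; values below the acceptable band are
    flagged as improvement targets.
    """
    compliance = fset.compliance()
    rows = []
    for v in fset.values():
        s = summaries.get(v.indicator_id)
        if s is not None and s.indicator_id != v.indicator_id:
            raise ValueError("summary/indicator id mismatch")
        rank = None
        if v.value is not None and s is not None and s.defined_values:
            rank = percentile_rank(v.value, s.defined_values)
        cls = compliance.get(v.indicator_id)
        rows.append({
            "indicator_id": v.indicator_id,
            "value": v.value,
            "numerator": v.numerator,
            "denominator": v.denominator,
            "regional_median": s.median if s else None,
            "regional_q1": s.q1 if s else None,
            "regional_q3": s.q3 if s else None,
            "percentile_rank": rank,
            "compliance_class": cls.value if cls else "",
            "improvement_target": bool(cls and cls.value == "non_compliant"),
            "flags": ";".join(v.flags),
        })
    df = pd.DataFrame(rows)

    lines = [f"Facility {fset.facility_id} — antibiotic-use indicators, {fset.year}",
             "=" * 60]
    for row in rows:
        val = "not computable" if row["value"] is None else f"{row['value']:.2f}"
        line = f"{row['indicator_id']:>5}: {val:>15}"
        if row["regional_median"] is not None:
            line += (f"  region median {row['regional_median']:.2f}"
                     f" (IQR {row['regional_q1']:.2f}–{row['regional_q3']:.2f})")
        if row["percentile_rank"] is not None:
            line += f"  pct {row['percentile_rank']:.0f}"
        if row["compliance_class"]:
            line += f"  [{row['compliance_class']}]"
        if row["improvement_target"]:
            line += "  << improvement target"
        if row["value"] is None and row["flags"]:
            line += f"  ({row['flags']})"
        lines.append(line)
    return df, "\n".join(lines)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """Fatal pipeline failure (unreadable inputs or failed validation)."""


@dataclass
class PipelineConfig:
    dispensings: str
    stays: str
    events: str
    year: int
    out_dir: str
    ddd_reference: Optional[str] = None    # YAML path; None = shipped default
    pack_reference: Optional[str] = None
    targets: Optional[str] = None
    date_format: Optional[str] = None
    dedupe: bool = False
    uc_window_days: int = DEFAULT_UC_WINDOW_DAYS
    lookback_days: int = DEFAULT_LOOKBACK_DAYS
    min_facilities: int = 2
    suppression_threshold: float = 0
    fail_on_validation_error: bool = True


def run_pipeline(config: PipelineConfig) -> dict:
    """Claims CSVs -> facility indicator table, regional summary, reports.

    Deterministic: identical inputs and config produce identical outputs.
    Returns the paths written.  Raises :class:`PipelineError` on unreadable
    inputs or (by default) on validation errors.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dialect = CsvDialect(date_format=config.date_format)
    try:
        dataset, report = load_dataset(config.dispensings, config.stays,
                                       config.events, config.year, dialect)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"cannot read inputs: {exc}") from exc

    logger.info("loaded %s dispensings, %s stays, %s events",
                len(dataset.dispensings), len(dataset.stays), len(dataset.events))
    for issue in report.errors + report.warnings:
        logger.log(logging.ERROR if issue.severity == "error" else logging.WARNING,
                   "[%s:%s] %s: %s", issue.table, issue.record_id, issue.rule, issue.message)
    (out_dir / "validation.txt").write_text(report.summary() + "\n", encoding="utf-8")
    if not report.passed and config.fail_on_validation_error:
        raise PipelineError(f"validation failed with {len(report.errors)} error(s); "
                            f"see {out_dir / 'validation.txt'}")

    if config.dedupe:
        before = len(dataset.dispensings)
        dataset = dataset.deduplicated()
        logger.info("dedupe removed %d dispensing rows", before - len(dataset.dispensings))
    if not any(d.dispense_date.year < config.year for d in dataset.dispensings):
        logger.warning("no look-back dispensings before %d: PI3 may undercount "
                       "repeat quinolone courses", config.year)

    ddd_ref = DddReference.from_yaml(config.ddd_reference) if config.ddd_reference else None
    pack_ref = PackReference.from_yaml(config.pack_reference) if config.pack_reference else None
    targets = load_targets_yaml(config.targets) if config.targets else load_default_targets()

    facility_ids = sorted({s.facility_id for s in dataset.stays})
    fsets = [
        compute_facility_set(dataset, fid, config.year, ddd_ref=ddd_ref,
                             pack_ref=pack_ref, targets=targets,
                             uc_window_days=config.uc_window_days,
                             lookback_days=config.lookback_days,
                             suppression_threshold=config.suppression_threshold)
        for fid in facility_ids
    ]

    rows = []
    for fset in fsets:
        compliance = fset.compliance()
        for v in fset.values():
            cls = compliance.get(v.indicator_id)
            rows.append({
                "facility_id": fset.facility_id,
                "indicator_id": v.indicator_id,
                "numerator": v.numerator,
                "denominator": v.denominator,
                "value": v.value,
                "compliance_class": cls.value if cls else "",
                "flags": ";".join(v.flags),
            })
    indicators_df = pd.DataFrame(rows)
    indicators_path = out_dir / "facility_indicators.csv"
    indicators_df.to_csv(indicators_path, index=False)

    summaries = {}
    summary_rows = []
    for ind_id in ALL_INDICATOR_IDS:
        vals = [v for fset in fsets for v in fset.values() if v.indicator_id == ind_id]
        s = summarize_region(vals, min_n=config.min_facilities)
        summaries[ind_id] = s
        summary_rows.append({
            "indicator_id": ind_id,
            "n_facilities": s.n_defined,
            "n_undefined": s.n_undefined,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
        })
    summary_path = out_dir / "regional_summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary_path, index=False)

    report_dir = out_dir / "reports"
    report_dir.mkdir(exist_ok=True)
    report_paths = []
    for fset in fsets:
        df, text = facility_report(fset, summaries)
        csv_path = report_dir / f"report_{fset.facility_id}.csv"
        txt_path = report_dir / f"report_{fset.facility_id}.txt"
        df.to_csv(csv_path, index=False)
        txt_path.write_text(text + "\n", encoding="utf-8")
        report_paths.append(txt_path)

    logger.info("wrote %d facility sets and the regional summary to %s",
                len(fsets), out_dir)
    return {
        "facility_indicators": indicators_path,
        "regional_summary": summary_path,
        "validation": out_dir / "validation.txt",
        "reports": report_paths,
        "facility_sets": fsets,
        "summaries": summaries,
    }
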