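"""ATC hierarchy matching, indicator drug classes, DDDs, route categories,
and package-based treatment-duration estimation.

Reimbursement claims carry ATC codes and package counts but no treatment
duration and no clinical context, so two reference tables bridge the gap:

* a DDD reference (WHO defined daily doses + unit strengths) to convert a
  dispensing into DDDs;
* a pack reference (units per package, assumed units per day) to *estimate*
  a course duration in days from the number of packages dispensed.

Both are shipped as editable YAML keyed by 7-character ATC code; the shipped
values are plausible defaults for the drugs the indicators name, meant to be
replaced with a curated national table in production use.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Union

import yaml

from .claims import DispensingRecord, Route, is_valid_atc

__all__ = [
    "DrugClass",
    "CLASS_PREFIXES",
    "PI7_DRUG_CODES",
    "RouteCategory",
    "DddEntry",
    "DddReference",
    "PackEntry",
    "PackReference",
    "MissingAtcError",
    "ReferenceConfigError",
    "atc_matches",
    "in_class",
    "total_ddd",
    "estimate_duration_days",
    "route_category",
    "load_default_ddd_reference",
    "load_default_pack_reference",
]


class DrugClass(Enum):
    """Drug-class sets used by the indicator definitions."""

    ALL_ABX = "ALL_ABX"              # systemic antibacterials
    AMC = "AMC"                      # amoxicillin/clavulanate
    CEPH = "CEPH"                    # cephalosporins
    FQ = "FQ"                        # (fluoro)quinolones
    MLSK = "MLSK"                    # macrolides, lincosamides, streptogramins, ketolides
    AMOX = "AMOX"                    # amoxicillin
    NITROFURANTOIN = "NITROFURANTOIN"
    FOSFOMYCIN_TROM = "FOSFOMYCIN_TROM"
    PIVMECILLINAM = "PIVMECILLINAM"
    SXT = "SXT"                      # sulfamethoxazole/trimethoprim
    NSAID = "NSAID"                  # systemic NSAIDs
    FLU_VACCINE = "FLU_VACCINE"      # influenza vaccines
    PI7_LIST = "PI7_LIST"            # drugs monitored for prolonged courses


#: The eight drugs monitored for prolonged courses: amoxicillin,
#: amoxicillin/clavulanate, cefuroxime, cefpodoxime, roxithromycin,
#: clarithromycin, pristinamycin, nitrofurantoin.
PI7_DRUG_CODES: tuple = (
    "J01CA04", "J01CR02", "J01DC02", "J01DD13",
    "J01FA06", "J01FA09", "J01FG01", "J01XE01",
)

CLASS_PREFIXES: Mapping[DrugClass, tuple] = {
    DrugClass.ALL_ABX: ("J01",),
    DrugClass.AMC: ("J01CR02",),
    DrugClass.CEPH: ("J01D",),
    DrugClass.FQ: ("J01M",),
    DrugClass.MLSK: ("J01F",),
    DrugClass.AMOX: ("J01CA04",),
    DrugClass.NITROFURANTOIN: ("J01XE01",),
    DrugClass.FOSFOMYCIN_TROM: ("J01XX01",),
    DrugClass.PIVMECILLINAM: ("J01CA08",),
    DrugClass.SXT: ("J01EE01",),
    DrugClass.NSAID: ("M01A",),
    DrugClass.FLU_VACCINE: ("J07BB",),
    DrugClass.PI7_LIST: PI7_DRUG_CODES,
}


class RouteCategory(Enum):
    ORAL = "oral"
    PARENTERAL = "parenteral"
    OTHER = "other"


def atc_matches(code: str, prefix: str) -> bool:
    """True iff *code* falls under *prefix* in the ATC hierarchy."""
    if not is_valid_atc(code):
        raise ValueError(f"invalid ATC code: {code!r}")
    if not is_valid_atc(prefix):
        raise ValueError(f"invalid ATC prefix: {prefix!r}")
    return code.startswith(prefix)


def in_class(record: Union[DispensingRecord, str], class_id: DrugClass) -> bool:
    """True iff the record's ATC code matches any prefix of the class set."""
    code = record.atc_code if isinstance(record, DispensingRecord) else record
    try:
        prefixes = CLASS_PREFIXES[class_id]
    except KeyError:
        raise ValueError(f"unknown drug class: {class_id!r}") from None
    return any(atc_matches(code, p) for p in prefixes)


def route_category(route: Route) -> RouteCategory:
    """IV/IM/SC are parenteral; anything not clearly oral/parenteral is other."""
    if route is Route.ORAL:
        return RouteCategory.ORAL
    if route in (Route.IV, Route.IM, Route.SC):
        return RouteCategory.PARENTERAL
    return RouteCategory.OTHER


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

class MissingAtcError(LookupError):
    """An ATC code is absent from a reference table; carries the code."""

    def __init__(self, code: str, table: str):
        super().__init__(f"ATC code {code} not found in {table} reference")
        self.code = code


class ReferenceConfigError(ValueError):
    """A reference config file contains a non-positive or malformed value."""


@dataclass(frozen=True)
class DddEntry:
    ddd_grams: float          # WHO defined daily dose (g, or units for unit-dosed)
    unit_strength_grams: float  # mass per dispensed unit (tablet, vial, sachet)
    units_per_package: Optional[int] = None  # fallback when the claim lacks it


@dataclass(frozen=True)
class PackEntry:
    units_per_package: int
    units_per_day: float      # assumed posology used for duration estimation


class DddReference:
    def __init__(self, entries: Mapping[str, DddEntry]):
        for code, e in entries.items():
            if e.ddd_grams <= 0 or e.unit_strength_grams <= 0:
                raise ReferenceConfigError(f"non-positive DDD/strength for {code}")
        self._entries = dict(entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> DddEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise MissingAtcError(code, "DDD") from None

    @classmethod
    def from_yaml(cls, path) -> "DddReference":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "DddReference":
        entries = {}
        for code, row in raw.items():
            entries[str(code)] = DddEntry(
                ddd_grams=float(row["ddd_grams"]),
                unit_strength_grams=float(row["unit_strength_grams"]),
                units_per_package=int(row["units_per_package"]) if "units_per_package" in row else None,
            )
        return cls(entries)


class PackReference:
    def __init__(self, entries: Mapping[str, PackEntry]):
        for code, e in entries.items():
            if e.units_per_package <= 0 or e.units_per_day <= 0:
                raise ReferenceConfigError(
                    f"non-positive package content or daily units for {code}")
        self._entries = dict(entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> PackEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise MissingAtcError(code, "pack") from None

    @classmethod
    def from_yaml(cls, path) -> "PackReference":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "PackReference":
        entries = {}
        for code, row in raw.items():
            entries[str(code)] = PackEntry(
                units_per_package=int(row["units_per_package"]),
                units_per_day=float(row["units_per_day"]),
            )
        return cls(entries)


def _data_text(name: str) -> str:
    return resources.files("abxstew.data").joinpath(name).read_text(encoding="utf-8")


def load_default_ddd_reference() -> DddReference:
    """The DDD reference shipped with the package (illustrative defaults)."""
    return DddReference._from_mapping(yaml.safe_load(_data_text("ddd_reference.yaml")))


def load_default_pack_reference() -> PackReference:
    """The pack reference shipped with the package (illustrative defaults)."""
    return PackReference._from_mapping(yaml.safe_load(_data_text("pack_reference.yaml")))


# ---------------------------------------------------------------------------
# Per-record computations
# ---------------------------------------------------------------------------

def total_ddd(record: DispensingRecord, ddd_ref: DddReference) -> float:
    """DDDs in one dispensing: n_packages x units/package x strength / DDD.

    Raises :class:`MissingAtcError` when the code is absent from the
    reference; callers exclude such records from DDD-based metrics and
    surface a coverage warning.
    """
    entry = ddd_ref[record.atc_code]
    upp = record.units_per_package
    if upp is None:
        upp = entry.units_per_package
    if upp is None:
        raise MissingAtcError(record.atc_code, "DDD (units per package)")
    return record.n_packages * upp * entry.unit_strength_grams / entry.ddd_grams


def estimate_duration_days(record: DispensingRecord, pack_ref: PackReference) -> float:
    """Estimated course duration in days from the quantity dispensed.

    Duration is not recorded in reimbursement claims; it is approximated as
    n_packages x units/package / assumed units per day.  Units per package
    come from the claim when present, else from the pack reference.
    """
    entry = pack_ref[record.atc_code]
    upp = record.units_per_package if record.units_per_package is not None else entry.units_per_package
    return record.n_packages * upp / entry.units_per_day
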