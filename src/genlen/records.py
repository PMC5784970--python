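"""Compilation of multi-source life-history records into per-species estimates.

Raw literature records arrive as one row per (species, parameter, source):
ages at female sexual maturity, gestation length, age at first reproduction
(AFR), age at last reproduction (ALR) or maximum longevity as its proxy, and
adult body mass.  Each record may be a point value or a range, in days,
months, years, grams or kilograms, and carries a wild/captive/unknown
provenance flag.

Compilation rules:

* AFR — direct estimates preferred; otherwise female maturity + gestation,
  paired within a source where possible.  Ranges resolved to their central
  value.  The median across candidate estimates is taken and rounded *up*
  to the nearest day.  Male-only maturity records are never used.
* ALR — direct ALR records preferred over longevity proxies within a
  provenance class.  Records are treated as wild only when flagged wild;
  unknown provenance is pooled with captive (precautionary).  Ranges
  resolved to their upper bound, and the maximum across sources is taken,
  separately for the wild and captive classes.
* Body mass — median across sources, in grams.

Conventions: 1 year = 365.25 days, 1 month = 365.25/12 days.  The ceiling
applied to AFR absorbs a small numerical tolerance so that a value entered
in months or years compiles to the same day count as its day-denominated
equivalent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

_TIME_FACTORS = {"days": 1.0, "months": DAYS_PER_MONTH, "years": DAYS_PER_YEAR}
_MASS_FACTORS = {"g": 1.0, "kg": 1000.0}

#: Parameters describing an age or duration (time units required).
TIME_PARAMETERS = frozenset(
    {"maturity_female", "maturity_male", "gestation", "afr", "alr", "longevity"}
)
PARAMETERS = TIME_PARAMETERS | {"mass"}
PROVENANCES = ("wild", "captive", "unknown")

# Tolerance (days) absorbed by the ceiling so unit round-trips through
# months/years do not spuriously bump AFR by one day.
_CEIL_TOL = 1e-6


def canonical_name(name: str) -> str:
    """Normalise a binomial: underscores to spaces, collapsed whitespace,
    first letter capitalised, remainder lower case."""
    cleaned = " ".join(str(name).replace("_", " ").split())
    return cleaned.capitalize()


@dataclass(frozen=True)
class SourceRecord:
    """One literature estimate of one life-history parameter for one species.

    Either ``value`` or the (``value_min``, ``value_max``) pair must be set.
    """

    species: str
    genus: str
    family: str
    parameter: str
    unit: str
    provenance: str = "unknown"
    source_id: str = ""
    value: float | None = None
    value_min: float | None = None
    value_max: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"{self._tag()}: unknown parameter {self.parameter!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"{self._tag()}: unknown provenance {self.provenance!r}")
        if self.parameter == "mass":
            if self.unit not in _MASS_FACTORS:
                raise ValueError(f"{self._tag()}: mass requires a mass unit, got {self.unit!r}")
        elif self.unit not in _TIME_FACTORS:
            raise ValueError(f"{self._tag()}: age requires a time unit, got {self.unit!r}")
        if self.is_range:
            if self.value is not None:
                raise ValueError(f"{self._tag()}: give either a value or a range, not both")
            if self.value_min is None or self.value_max is None:
                raise ValueError(f"{self._tag()}: incomplete range")
            if self.value_min > self.value_max:
                raise ValueError(
                    f"{self._tag()}: inverted range ({self.value_min} > {self.value_max})"
                )
            if self.value_min <= 0:
                raise ValueError(f"{self._tag()}: non-positive range bound")
        else:
            if self.value is None:
                raise ValueError(f"{self._tag()}: missing value")
            if self.value <= 0:
                raise ValueError(f"{self._tag()}: non-positive value {self.value}")

    @property
    def is_range(self) -> bool:
        return self.value is None

    def _tag(self) -> str:
        return f"record[{self.species}/{self.parameter}/{self.source_id or '?'}]"


def resolve_range(value_min: float, value_max: float, rule: str) -> float:
    """Collapse a reported range to a point estimate.

    ``rule='central'`` returns the midpoint (AFR-type parameters);
    ``rule='upper'`` returns the upper bound (longevity-type parameters,
    avoiding bias from life-expectancy style reports).
    """
    if value_min > value_max:
        raise ValueError(f"inverted range: {value_min} > {value_max}")
    if value_min <= 0:
        raise ValueError("range bounds must be positive")
    if rule == "central":
        return 0.5 * (value_min + value_max)
    if rule == "upper":
        return float(value_max)
    raise ValueError(f"unknown range rule {rule!r}")


def record_days(record: SourceRecord, rule: str) -> float:
    """Point estimate of a time-valued record, converted to days."""
    if record.parameter == "mass":
        raise ValueError(f"{record._tag()}: not a time-valued record")
    if record.is_range:
        try:
            v = resolve_range(record.value_min, record.value_max, rule)
        except ValueError as exc:
            raise ValueError(f"{record._tag()}: {exc}") from exc
    else:
        v = float(record.value)
    return v * _TIME_FACTORS[record.unit]


def record_grams(record: SourceRecord) -> float:
    if record.parameter != "mass":
        raise ValueError(f"{record._tag()}: not a mass record")
    v = (
        resolve_range(record.value_min, record.value_max, "central")
        if record.is_range
        else float(record.value)
    )
    return v * _MASS_FACTORS[record.unit]


def _ceil_days(days: float) -> int:
    return int(math.ceil(days - _CEIL_TOL))


def compile_afr(records: Iterable[SourceRecord]) -> int | None:
    """Median age at first reproduction, in days, rounded up.

    Direct AFR estimates are used when present.  Otherwise each source
    contributing both a female-maturity and a gestation record yields a
    candidate AFR = maturity + gestation; if no source carries both, a
    single candidate is formed from the median maturity plus the median
    gestation.  Male maturity records are ignored throughout.  Returns
    ``None`` when no usable records exist (AFR-missing species).
    """
    records = list(records)
    direct = [record_days(r, "central") for r in records if r.parameter == "afr"]
    if direct:
        candidates = direct
    else:
        maturity: dict[str, list[float]] = {}
        gestation: dict[str, list[float]] = {}
        for r in records:
            if r.parameter == "maturity_female":
                maturity.setdefault(r.source_id, []).append(record_days(r, "central"))
            elif r.parameter == "gestation":
                gestation.setdefault(r.source_id, []).append(record_days(r, "central"))
        paired = [
            float(np.mean(maturity[s])) + float(np.mean(gestation[s]))
            for s in sorted(maturity.keys() & gestation.keys())
        ]
        if paired:
            candidates = paired
        elif maturity and gestation:
            all_mat = [v for vals in maturity.values() for v in vals]
            all_gest = [v for vals in gestation.values() for v in vals]
            candidates = [float(np.median(all_mat)) + float(np.median(all_gest))]
        else:
            return None
    return _ceil_days(float(np.median(candidates)))


def _class_alr_days(records: Sequence[SourceRecord]) -> float | None:
    direct = [r for r in records if r.parameter == "alr"]
    pool = direct if direct else [r for r in records if r.parameter == "longevity"]
    if not pool:
        return None
    return max(record_days(r, "upper") for r in pool)


def compile_alr(records: Iterable[SourceRecord]) -> tuple[float | None, float | None]:
    """(wild, captive) age at last reproduction in days.

    Within each provenance class, direct ALR records take precedence over
    longevity proxies; ranges resolve to their upper bound and the maximum
    across sources is returned.  Unknown provenance is pooled with captive.
    A class with no records yields ``None`` (legal missing value).
    """
    records = list(records)
    wild = [r for r in records if r.provenance == "wild"]
    captive = [r for r in records if r.provenance in ("captive", "unknown")]
    return _class_alr_days(wild), _class_alr_days(captive)


def compile_mass(records: Iterable[SourceRecord]) -> float | None:
    masses = [record_grams(r) for r in records if r.parameter == "mass"]
    return float(np.median(masses)) if masses else None


RECORD_COLUMNS = [
    "species",
    "genus",
    "family",
    "parameter",
    "value",
    "value_min",
    "value_max",
    "unit",
    "provenance",
    "source_id",
]


def records_from_frame(frame: pd.DataFrame) -> list[SourceRecord]:
    """Validate a raw record table (one row per record) into SourceRecords."""
    out = []
    for row in frame.itertuples(index=False):
        def _num(x):
            return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

        out.append(
            SourceRecord(
                species=canonical_name(row.species),
                genus=canonical_name(row.genus),
                family=canonical_name(row.family),
                parameter=str(row.parameter),
                unit=str(row.unit),
                provenance=str(row.provenance),
                source_id=str(row.source_id),
                value=_num(row.value),
                value_min=_num(row.value_min),
                value_max=_num(row.value_max),
            )
        )
    return out


def read_records(path) -> pd.DataFrame:
    """Read a raw record CSV (UTF-8, header required)."""
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"record file lacks columns: {sorted(missing)}")
    return frame


COMPILED_COLUMNS = [
    "species",
    "genus",
    "family",
    "afr_days",
    "alr_wild_days",
    "alr_captive_days",
    "mass_g",
    "n_sources_afr",
    "n_sources_alrw",
    "n_sources_alrc",
]


def compile_database(records: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Compile a raw record table into one row per species.

    ``taxonomy`` needs columns species/genus/family and must be free of
    conflicting duplicates.  Records whose species is absent from the
    taxonomy are reported via a warning and skipped.
    """
    tax = taxonomy.copy()
    for col in ("species", "genus", "family"):
        if col not in tax.columns:
            raise ValueError(f"taxonomy lacks column {col!r}")
        tax[col] = tax[col].map(canonical_name)
    dup = tax.drop_duplicates()
    if dup["species"].duplicated().any():
        bad = sorted(dup.loc[dup["species"].duplicated(), "species"])
        raise ValueError(f"conflicting taxonomy rows for: {bad}")
    tax = dup.set_index("species")

    recs = records_from_frame(records) if len(records) else []
    by_species: dict[str, list[SourceRecord]] = {}
    for r in recs:
        by_species.setdefault(r.species, []).append(r)

    unresolved = sorted(set(by_species) - set(tax.index))
    if unresolved:
        warnings.warn(f"records for species absent from taxonomy: {unresolved}")

    rows = []
    for species in sorted(set(by_species) & set(tax.index)):
        rs = by_species[species]
        afr = compile_afr(rs)
        alrw, alrc = compile_alr(rs)
        mass = compile_mass(rs)
        n_afr = len({r.source_id for r in rs if r.parameter in ("afr", "maturity_female", "gestation")})
        n_alrw = len({r.source_id for r in rs if r.parameter in ("alr", "longevity") and r.provenance == "wild"})
        n_alrc = len(
            {r.source_id for r in rs if r.parameter in ("alr", "longevity") and r.provenance != "wild"}
        )
        rows.append(
            {
                "species": species,
                "genus": tax.loc[species, "genus"],
                "family": tax.loc[species, "family"],
                "afr_days": afr,
                "alr_wild_days": alrw,
                "alr_captive_days": alrc,
                "mass_g": mass,
                "n_sources_afr": n_afr if afr is not None else 0,
                "n_sources_alrw": n_alrw if alrw is not None else 0,
                "n_sources_alrc": n_alrc if alrc is not None else 0,
            }
        )
    return pd.DataFrame(rows, columns=COMPILED_COLUMNS)
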