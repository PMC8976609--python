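"""Historical population growth rates and best-correlation founder-mutation dating.

A linkage-disequilibrium-based mutation-age estimator (an external Bayesian
MCMC program) needs an assumed population growth rate.  Chinese census
records exist for seven historical time points spanning 684 B.C. to 1949
A.D.; each yields an average annual growth rate via

    X = ((P2 - P1) / P1) ** (1 / n) - 1

with P1 the historical count, P2 the present population (1.4 billion) and n
the years elapsed.  Note the numerator is the population *increase* P2 - P1,
not P2: this is the printed form of the equation and is what reproduces the
published per-mille rates; the conventional compound-growth form
(P2 / P1) ** (1/n) - 1 is available behind a flag.

Running the external age estimator once per growth rate gives seven
candidate ages n-hat.  The selection rule keeps the time point whose actual
elapsed time n best agrees with the age estimated under its own growth rate
(minimum |n-hat - n|); ties break toward the smaller n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "PRESENT_POPULATION",
    "GrowthRateRow",
    "AgeSelection",
    "growth_rate",
    "per_mille",
    "read_population_records",
    "bundled_population_records",
    "compute_growth_rates",
    "select_best_rate",
    "years_to_calendar",
]

logger = logging.getLogger(__name__)

#: Chinese population in 2020
PRESENT_POPULATION = 1.4e9

_UNIT_FACTORS = {"persons": 1.0, "thousand": 1e3, "million": 1e6, "billion": 1e9}


@dataclass(frozen=True)
class GrowthRateRow:
    label: str
    population: float  # absolute persons
    years_till_now: int
    growth_rate: float | None = None  # per-year fraction
    estimated_age: float | None = None  # years, from the external estimator

    @property
    def growth_rate_per_mille(self) -> float | None:
        return None if self.growth_rate is None else per_mille(self.growth_rate)


@dataclass(frozen=True)
class AgeSelection:
    chosen: GrowthRateRow
    discrepancy: float


def growth_rate(p1: float, p2: float, n: int, conventional: bool = False) -> float:
    """Average annual growth rate from a historical population p1 to present p2.

    Default form: ``((p2 - p1) / p1) ** (1/n) - 1`` (increase over baseline).
    ``conventional=True`` uses ``(p2 / p1) ** (1/n) - 1`` instead.
    """
    if p1 <= 0:
        raise DomainError(f"historical population must be > 0, got {p1}")
    if n < 1:
        raise DomainError(f"elapsed years must be >= 1, got {n}")
    ratio = p2 / p1 if conventional else (p2 - p1) / p1
    if ratio <= 0:
        raise DomainError("negative or zero growth is outside this equation's domain")
    return ratio ** (1.0 / n) - 1.0


def per_mille(x: float, decimals: int = 2) -> float:
    """Display convention: per-year fraction -> per mille, rounded to two decimals."""
    return round(x * 1000, decimals)


def read_population_records(path: str | Path) -> list[GrowthRateRow]:
    """Read a historical-population table.

    Columns: ``label, population, population_unit, years_till_now`` and
    optionally ``estimated_age``.  ``population_unit`` is one of persons,
    thousand, million, billion.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"label", "population", "population_unit", "years_till_now"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {', '.join(sorted(missing))}")
    rows = []
    for rec in df.to_dict("records"):
        unit = str(rec["population_unit"]).strip().lower()
        if unit not in _UNIT_FACTORS:
            raise ConfigurationError(f"unknown population unit {unit!r}")
        est = rec.get("estimated_age")
        rows.append(
            GrowthRateRow(
                label=str(rec["label"]),
                population=float(rec["population"]) * _UNIT_FACTORS[unit],
                years_till_now=int(rec["years_till_now"]),
                estimated_age=None if est is None or pd.isna(est) else float(est),
            )
        )
    return rows


def bundled_population_records() -> list[GrowthRateRow]:
    """The seven historical Chinese census records shipped with the package."""
    with resources.as_file(
        resources.files("brcascan.data") / "han_population_records.tsv"
    ) as path:
        return read_population_records(path)


def compute_growth_rates(
    rows: Sequence[GrowthRateRow],
    present_population: float = PRESENT_POPULATION,
    conventional: bool = False,
) -> list[GrowthRateRow]:
    """Fill the growth-rate field of each record from the present population."""
    return [
        replace(
            r,
            growth_rate=growth_rate(
                r.population, present_population, r.years_till_now, conventional=conventional
            ),
        )
        for r in rows
    ]


def select_best_rate(rows: Sequence[GrowthRateRow]) -> AgeSelection:
    """Pick the record whose externally estimated age best matches its elapsed time.

    Minimizes |estimated_age - years_till_now|; ties break toward smaller
    years_till_now (logged).
    """
    candidates = [r for r in rows if r.estimated_age is not None]
    if not candidates:
        raise DomainError("no records carry an estimated age")
    best = min(
        candidates, key=lambda r: (abs(r.estimated_age - r.years_till_now), r.years_till_now)
    )
    disc = abs(best.estimated_age - best.years_till_now)
    ties = [
        r
        for r in candidates
        if abs(r.estimated_age - r.years_till_now) == disc and r is not best
    ]
    if ties:
        logger.info("tie on discrepancy %.1f broken toward smaller elapsed time", disc)
    return AgeSelection(chosen=best, discrepancy=disc)


def years_to_calendar(age_years: int, present_year: int = 2020) -> str:
    """Convert an age in years to a calendar label, e.g. 2090 from 2020 -> "70 B.C.".

    The subtraction present_year - age_years is labelled directly; a
    non-positive result is Before Christ, with the boundary case 0 mapped to
    1 B.C. because there is no year zero.
    """
    if age_years < 0:
        raise DomainError("age must be >= 0")
    y = present_year - age_years
    if y > 0:
        return f"{y} A.D."
    if y == 0:
        return "1 B.C."
    return f"{-y} B.C."
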