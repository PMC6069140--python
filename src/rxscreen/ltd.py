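"""Lowest therapeutic dose (LTD) calculation.

The LTD — the smallest labeled daily dose that produces a clinically
effective outcome — serves as the point of departure, treated as analogous
to a LOAEL. Label doses in mg/day are converted to mg/kg-day using mean
body weights by one-year age bracket (22.5 kg at ages 6–7 up to 80 kg for
adults ≥18, the Exposure Factors Handbook mean). When a label covers an
age span, each one-year bracket is evaluated separately and the minimum
quotient is the LTD; the heaviest covered bracket usually wins. Doses the
label already states in mg/kg-day pass through unchanged. Regimens
restricted to special populations (renal/hepatic impairment, titration)
are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources

import pandas as pd

from .evidence import DoseRegimen, DoseUnits
from .rounding import round_sig, to_decimal

__all__ = [
    "BodyWeightTable",
    "load_body_weight_table",
    "lookup_body_weight",
    "daily_dose",
    "compute_ltd",
    "LTDResult",
]

ADULT_AGE = 18
_MIN_BRACKET_AGE = 6
_LTD_SIG_FIGS = 3


@dataclass(frozen=True)
class BodyWeightTable:
    """Mean weight (kg) per one-year age bracket; ``weights[a]`` is the
    bracket [a, a+1) for a in 6..17, plus the adult row keyed by 18."""

    weights: dict[int, Decimal]

    def __post_init__(self):
        expected = set(range(_MIN_BRACKET_AGE, ADULT_AGE + 1))
        if set(self.weights) != expected:
            raise ValueError("body-weight table must cover ages 6-7 ... 17-18 and >=18")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("body weights must be strictly positive")


def load_body_weight_table() -> BodyWeightTable:
    """Load the packaged age/weight resource."""
    with resources.files("rxscreen.data").joinpath("table2_bodyweights.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"age_low_years": int, "mean_weight_kg": str})
    return BodyWeightTable(
        {int(r.age_low_years): Decimal(r.mean_weight_kg) for r in df.itertuples()}
    )


_DEFAULT_TABLE: BodyWeightTable | None = None


def _default_table() -> BodyWeightTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_body_weight_table()
    return _DEFAULT_TABLE


def lookup_body_weight(age_years: float, table: BodyWeightTable | None = None) -> Decimal:
    """Mean body weight (kg) for the one-year bracket containing ``age_years``.

    Ages under 6 raise: labels dose those ages in mg/kg directly, so the
    per-weight conversion path does not apply.
    """
    if age_years < _MIN_BRACKET_AGE:
        raise ValueError(
            "no body-weight bracket below age 6; dosing for young children is "
            "labeled in mg/kg-day and passes through without conversion"
        )
    table = table or _default_table()
    bracket = min(int(math.floor(age_years)), ADULT_AGE)
    return table.weights[bracket]


def daily_dose(regimen: DoseRegimen) -> Decimal:
    """Total labeled dose over a 24-h day, in mg/day.

    Multi-dose schedules count the full daily amount (a 10 mg tablet taken
    four times a day is a 40 mg/day dose), not the per-tablet amount.
    """
    if regimen.units is DoseUnits.mg_per_kg_day:
        raise ValueError("mg/kg-day regimens bypass the daily-dose conversion")
    amount = to_decimal(regimen.amount_mg)
    if regimen.units is DoseUnits.mg_per_administration:
        return amount * regimen.administrations_per_day
    return amount


@dataclass(frozen=True)
class LTDResult:
    ltd_mg_kg_d: Decimal
    regimen_index: int
    age_bracket: int | None  # lower age of the winning bracket; None for pass-through
    candidates: tuple[tuple[int, int | None, Decimal], ...]  # (regimen, bracket, ltd)


def _covered_brackets(regimen: DoseRegimen) -> list[int]:
    if regimen.age_min_years >= ADULT_AGE:
        return [ADULT_AGE]
    lo = max(_MIN_BRACKET_AGE, int(math.floor(regimen.age_min_years)))
    hi = min(ADULT_AGE - 1, int(math.floor(regimen.age_max_years)))
    return list(range(lo, hi + 1))


def compute_ltd(
    regimens: list[DoseRegimen], table: BodyWeightTable | None = None
) -> LTDResult:
    """Lowest therapeutic dose in mg/kg-day across all usable regimens.

    Weight-normalised candidates are rounded to 3 significant figures (the
    precision at which screening tables report LTDs); mg/kg-day regimens
    pass through bit-identically. Ties keep the first regimen in label
    order; every candidate is retained in the result for audit.
    """
    table = table or _default_table()
    usable = [(i, r) for i, r in enumerate(regimens) if not r.special_population_only]
    if not usable:
        raise ValueError("no general-population dose: all regimens are special-population")

    candidates: list[tuple[int, int | None, Decimal]] = []
    for i, regimen in usable:
        if regimen.units is DoseUnits.mg_per_kg_day:
            candidates.append((i, None, to_decimal(regimen.amount_mg)))
            continue
        dose = daily_dose(regimen)
        brackets = _covered_brackets(regimen)
        if not brackets:
            raise ValueError(
                f"regimen {i}: age range below 6 years requires mg/kg-day dosing"
            )
        for bracket in brackets:
            ltd = round_sig(dose / table.weights[bracket], _LTD_SIG_FIGS)
            candidates.append((i, bracket, ltd))

    best = min(candidates, key=lambda c: c[2])
    return LTDResult(
        ltd_mg_kg_d=best[2],
        regimen_index=best[0],
        age_bracket=best[1],
        candidates=tuple(candidates),
    )
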