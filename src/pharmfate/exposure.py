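"""Consumption-based load estimation.

Regional drug statistics are reported as counts of defined daily doses
(DDD).  The annual consumed mass is simply

    mass [kg/y] = N_DDD x DDD [mg] x 1e-6,

and an expected raw-wastewater (influent) concentration follows from
apportioning the regional mass to one treatment plant by population share,
applying the excretion fraction, and diluting into the plant's wastewater
volume:

    C_expected [ng/L] = mass_kg x (served/region) x f_excreted x 1e12
                        / (served x V_percap x 365)

where V_percap is the per-capita wastewater production in L/person/day.
Because literature excretion fractions often conflict, the fraction is an
interval and C_expected is reported as low/mid/high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import Compound, ConsumptionRecord


def annual_mass(record: ConsumptionRecord) -> float:
    """Annual consumed mass in kg/year: ``n_ddd * ddd_mg / 1e6``."""
    return record.n_ddd * record.ddd_mg / 1e6


def table_mass_kg(record: ConsumptionRecord) -> int:
    """Annual mass rounded half-up to whole kg, the convention used in
    consumption tables."""
    return int(math.floor(annual_mass(record) + 0.5))


@dataclass(frozen=True)
class ExpectedInfluent:
    """Expected influent concentration band (ng/L) from an excretion
    interval."""

    low: float
    mid: float
    high: float


@dataclass(frozen=True)
class LoadEstimate:
    compound: str
    mass_kg_per_year: float
    expected_influent: ExpectedInfluent | None = None


def expected_influent(
    mass_kg_per_year: float,
    compound: Compound,
    *,
    population_served: int,
    region_population: int,
    wastewater_L_per_capita_day: float = 200.0,
) -> ExpectedInfluent | None:
    """Expected influent concentration band for one treatment plant.

    Returns ``None`` (an explicit "unavailable" marker, never zero) when the
    compound has no excretion fraction.
    """
    if population_served <= 0 or region_population <= 0:
        raise ValueError("populations must be positive")
    if population_served > region_population:
        raise ValueError("population served cannot exceed the region population")
    if wastewater_L_per_capita_day <= 0:
        raise ValueError("wastewater volume must be positive")
    if compound.f_excreted_unchanged is None:
        return None

    share = population_served / region_population
    volume_L_per_year = population_served * wastewater_L_per_capita_day * 365.0

    def conc(f: float) -> float:
        return mass_kg_per_year * share * f * 1e12 / volume_L_per_year

    low, high = compound.f_excreted_unchanged
    mid = (low + high) / 2.0
    return ExpectedInfluent(low=conc(low), mid=conc(mid), high=conc(high))


def load_estimates(
    records: list[ConsumptionRecord],
    compounds: dict[str, Compound],
    *,
    population_served: int | None = None,
    region_population: int | None = None,
    wastewater_L_per_capita_day: float = 200.0,
) -> list[LoadEstimate]:
    """Annual masses, plus expected influent bands when plant and region
    populations are configured."""
    out = []
    for rec in records:
        mass = annual_mass(rec)
        expected = None
        if population_served is not None and region_population is not None:
            compound = compounds.get(rec.compound)
            if compound is not None:
                expected = expected_influent(
                    mass,
                    compound,
                    population_served=population_served,
                    region_population=region_population,
                    wastewater_L_per_capita_day=wastewater_L_per_capita_day,
                )
        out.append(LoadEstimate(rec.compound, mass, expected))
    return out


def load_table(
    records: list[ConsumptionRecord],
    estimates: list[LoadEstimate],
) -> pd.DataFrame:
    """Consumption table: DDD count, DDD size, whole-kg annual mass, and the
    expected-influent band where available."""
    by_name = {e.compound: e for e in estimates}
    rows = []
    for rec in records:
        est = by_name[rec.compound]
        exp = est.expected_influent
        rows.append(
            {
                "compound": rec.compound,
                "n_ddd": rec.n_ddd,
                "ddd_mg": rec.ddd_mg,
                "consumption_kg_per_year": table_mass_kg(rec),
                "expected_influent_low_ng_L": None if exp is None else exp.low,
                "expected_influent_mid_ng_L": None if exp is None else exp.mid,
                "expected_influent_high_ng_L": None if exp is None else exp.high,
            }
        )
    return pd.DataFrame(rows)
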