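"""Closed-form phytolith accumulation-time model.

A well-mixed soil column accumulates phytoliths at a constant annual input
(cover x biomass x phytolith production fraction).  With zero dissolution
the time to reach a target mass fraction of the mixing-zone soil mass is
linear; with first-order dissolution at rate delta the stock follows
S(t) = (input/delta) * (1 - exp(-delta t)) and the threshold may be
unreachable when the steady state input/delta falls below the target.

Default scenario: 75% annual-grass cover, 200 g/m2/yr biomass, 4% phytolith
production, 1.5 g/cc bulk density over a 60 cm mixing zone, 0.30% threshold,
zero dissolution -> 6 g/m2/yr input, 900,000 g mixing-zone mass, 450 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

CM2_PER_M2 = 10_000.0


@dataclass
class AccumulationScenario:
    """Inputs to the accumulation-time model (per m^2 soil column)."""

    cover: float = 0.75  # grass cover fraction, [0, 1]
    biomass: float = 200.0  # annual biomass production, g/m2/yr
    production: float = 0.04  # phytolith production fraction, (0, 1)
    bulk_density: float = 1.5  # g/cm3
    depth: float = 60.0  # mixing-zone depth, cm
    threshold: float = 0.003  # target phytolith mass fraction, (0, 1)
    dissolution: float = 0.0  # first-order loss rate, fraction/yr, [0, 1)

    def validate(self) -> None:
        checks = [
            (0.0 <= self.cover <= 1.0, f"cover must be in [0, 1], got {self.cover}"),
            (self.biomass > 0, f"biomass must be positive, got {self.biomass}"),
            (0.0 < self.production < 1.0, f"production must be in (0, 1), got {self.production}"),
            (self.bulk_density > 0, f"bulk density must be positive, got {self.bulk_density}"),
            (self.depth > 0, f"depth must be positive, got {self.depth}"),
            (0.0 <= self.threshold < 1.0, f"threshold must be in [0, 1), got {self.threshold}"),
            (0.0 <= self.dissolution < 1.0, f"dissolution must be in [0, 1), got {self.dissolution}"),
        ]
        for ok, message in checks:
            if not ok:
                raise DomainError(message)


def annual_input(cover: float, biomass: float, production: float) -> float:
    """Annual phytolith input into the soil, g/m2/yr = cover x biomass x
    production fraction."""
    if not (0.0 <= cover <= 1.0):
        raise DomainError(f"cover must be in [0, 1], got {cover}")
    if biomass <= 0:
        raise DomainError(f"biomass must be positive, got {biomass}")
    if not (0.0 < production < 1.0):
        raise DomainError(f"production must be in (0, 1), got {production}")
    return cover * biomass * production


def mixing_zone_mass(bulk_density: float, depth: float) -> float:
    """Soil mass of the mixing zone beneath 1 m^2, in grams:
    bulk_density (g/cm3) x depth (cm) x 10,000 cm2/m2."""
    if bulk_density <= 0 or depth <= 0:
        raise DomainError("bulk density and depth must be positive")
    return bulk_density * depth * CM2_PER_M2


def time_to_threshold(scenario: AccumulationScenario) -> dict:
    """Years for the soil to reach the threshold phytolith content.

    Zero dissolution: t = threshold x mixing mass / annual input.  With
    dissolution delta > 0, t solves the linear-input/exponential-loss
    balance; ``reachable`` is False (years = inf) when the steady state
    input/delta is at or below the target stock.
    """
    scenario.validate()
    input_rate = annual_input(scenario.cover, scenario.biomass, scenario.production)
    mass = mixing_zone_mass(scenario.bulk_density, scenario.depth)
    target = scenario.threshold * mass
    result = {"input": input_rate, "mass": mass, "target_stock": target, "reachable": True}
    if target == 0:
        result["years"] = 0.0
        return result
    if input_rate == 0:
        result.update(years=math.inf, reachable=False)
        return result
    delta = scenario.dissolution
    if delta == 0:
        result["years"] = target / input_rate
        return result
    steady = input_rate / delta
    if steady <= target:
        result.update(years=math.inf, reachable=False)
        return result
    result["years"] = -math.log(1.0 - target / steady) / delta
    return result
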