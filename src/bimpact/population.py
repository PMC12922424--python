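"""Eligible-population projection under net prevalence growth.

The cohort grows by a constant net rate g = incidence − dropout each year.
Counts compound sequentially: each year's count is the *previous rounded
count* times (1 + g), rounded again.  Sequential rounding is what budget
holders actually plan with (whole patients each year) and, for a 173-patient
cohort at g = 0.05, yields 182, 191, 201, 211 — nearest-integer rounding
with halves away from zero (200.55 → 201, 211.05 → 211).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Union

import pandas as pd

from .model import PopulationModel


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def net_growth_rate(incidence_rate: float, dropout_rate: float) -> float:
    """Additive net growth: incidence − dropout, both annual fractions."""
    for name, rate in (("incidence_rate", incidence_rate), ("dropout_rate", dropout_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} {rate} outside [0, 1]")
    return incidence_rate - dropout_rate


@dataclass(frozen=True)
class PopulationProjection:
    """Patient counts per calendar year."""

    counts: Dict[int, Union[int, float]]
    growth_rate_used: float
    rounding_policy: str

    def count(self, year: int) -> Union[int, float]:
        return self.counts[year]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": list(self.counts), "count": list(self.counts.values())}
        )


def project_population(model: PopulationModel) -> PopulationProjection:
    """Project N(t) over the model horizon.

    The base year keeps ``base_count`` exactly.  Under rounding policy
    ``none`` this reduces to the closed form base × (1+g)^t; under
    ``nearest_half_away_from_zero`` each year is rounded before the next
    compounding step.
    """
    g = net_growth_rate(model.incidence_rate, model.dropout_rate)
    counts: Dict[int, Union[int, float]] = {}
    current: Union[int, float] = model.base_count
    for year in model.years:
        counts[year] = current
        nxt = current * (1.0 + g)
        current = (
            _round_half_away(nxt)
            if model.rounding_policy == "nearest_half_away_from_zero"
            else nxt
        )
    return PopulationProjection(
        counts=counts,
        growth_rate_used=g,
        rounding_policy=model.rounding_policy,
    )
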