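"""The budget impact engine.

For each calendar year t the engine prices both scenarios over the
projected population N(t):

    arm cost        A_k(t) = N(t) · s_k(t) · c_k(t)
    scenario total  C(t)   = Σ_k A_k(t)
    incremental     ΔC(t)  = C_proj(t) − C_base(t)      (negative = saving)
    per patient     ΔC(t) / N(t), rounded to integer QAR

N(t) is an integer patient count but the arm-level population s_k·N stays
fractional — market shares split budgets, not people.  No discounting or
inflation adjustment is applied: budget impact analyses report undiscounted
nominal annual outlays over a short horizon.  The cumulative impact is the
exact sum of the yearly incrementals.

Each year's per-patient impact is classified against the affordability
threshold T (a multiple of GDP per capita, or an explicit override):
``saving`` (≤ 0), ``affordable`` (≤ T), ``borderline`` (≤ (1+tol)·T),
``unacceptable`` (beyond).
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .model import AffordabilityThreshold, ModelSpec
from .population import _round_half_away, project_population


class Affordability(str, enum.Enum):
    SAVING = "saving"
    AFFORDABLE = "affordable"
    BORDERLINE = "borderline"
    UNACCEPTABLE = "unacceptable"


def scenario_annual_cost(
    n: float, shares: Mapping[str, float], costs: Mapping[str, float]
) -> Tuple[Dict[str, float], float]:
    """Price one scenario-year: per-arm costs N·s_k·c_k and their total."""
    share_sum = sum(shares.values())
    if not math.isclose(share_sum, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"shares sum to {share_sum!r}, expected 1")
    arm_costs: Dict[str, float] = {}
    for arm_id, share in shares.items():
        if share > 0 and arm_id not in costs:
            raise KeyError(f"no unit cost for arm {arm_id!r} with share {share}")
        arm_costs[arm_id] = n * share * costs.get(arm_id, 0.0)
    return arm_costs, sum(arm_costs.values())


def baseline_annual_cost(n: float, year: int, spec: ModelSpec) -> float:
    """Total baseline-scenario cost for one year."""
    if year not in spec.baseline.shares:
        raise KeyError(f"baseline scenario undefined for year {year}")
    shares = spec.baseline.shares[year]
    if not shares:
        raise ValueError(f"baseline scenario has no shares in year {year}")
    table = spec.cost_table("baseline")
    costs = {a: table.cost(a, year) for a, s in shares.items() if s > 0}
    _, total = scenario_annual_cost(n, shares, costs)
    return total


def incremental_impact(projected_total: float, baseline_total: float) -> float:
    """ΔC = projected − baseline; negative values are savings."""
    return projected_total - baseline_total


def per_patient_impact(incremental: float, n: float) -> int:
    """ΔC / N in integer QAR, halves rounded away from zero."""
    if n <= 0:
        raise ValueError(f"patient count must be positive, got {n}")
    return _round_half_away(incremental / n)


def cumulative_impact(rows: Sequence["YearlyBudgetRow"]) -> float:
    """Exact sum of yearly incrementals."""
    if not rows:
        raise ValueError("no yearly rows to accumulate")
    return sum(row.incremental for row in rows)


def assess_affordability(
    per_patient: float, threshold: AffordabilityThreshold
) -> Affordability:
    """Classify a per-patient yearly impact against the threshold band."""
    t = threshold.effective
    if per_patient <= 0:
        return Affordability.SAVING
    if per_patient <= t:
        return Affordability.AFFORDABLE
    if per_patient <= (1.0 + threshold.tolerance_fraction) * t:
        return Affordability.BORDERLINE
    return Affordability.UNACCEPTABLE


@dataclass(frozen=True)
class YearlyBudgetRow:
    year: int
    n: float
    arm_costs: Dict[str, float]
    projected_total: float
    baseline_total: float
    incremental: float
    per_patient: int
    affordability: Affordability


@dataclass(frozen=True)
class BudgetImpactResult:
    """Per-year rows plus the cumulative impact of one evaluated spec."""

    rows: List[YearlyBudgetRow]
    cumulative: float
    spec_digest: str = field(default="")

    def row(self, year: int) -> YearlyBudgetRow:
        for r in self.rows:
            if r.year == year:
                return r
        raise KeyError(f"no result row for year {year}")

    def incrementals(self) -> Dict[int, float]:
        return {r.year: r.incremental for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout mirroring a published BIA table, integer QAR."""
        arm_ids = sorted({a for r in self.rows for a in r.arm_costs})
        records = []
        for r in self.rows:
            rec = {"year": r.year, "n": r.n}
            for arm_id in arm_ids:
                rec[f"cost_{arm_id}"] = round(r.arm_costs.get(arm_id, 0.0))
            rec.update(
                projected_total=round(r.projected_total),
                baseline_total=round(r.baseline_total),
                incremental=round(r.incremental),
                per_patient=r.per_patient,
                affordability=r.affordability.value,
            )
            records.append(rec)
        return pd.DataFrame(records)


def spec_digest(spec: ModelSpec) -> str:
    payload = spec.model_dump_json(exclude_none=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_budget_impact(spec: ModelSpec) -> BudgetImpactResult:
    """Evaluate the full model: population → yearly costs → impacts.

    Drives the population projection, prices baseline and projected
    scenarios each year, and derives incremental, per-patient and
    affordability columns plus the cumulative impact.
    """
    projection = project_population(spec.population)
    proj_table = spec.cost_table("projected")
    rows: List[YearlyBudgetRow] = []
    for year in spec.population.years:
        n = projection.count(year)
        shares = spec.projected.shares[year]
        costs = {a: proj_table.cost(a, year) for a, s in shares.items() if s > 0}
        arm_costs, projected_total = scenario_annual_cost(n, shares, costs)
        baseline_total = baseline_annual_cost(n, year, spec)
        incremental = incremental_impact(projected_total, baseline_total)
        per_patient = per_patient_impact(incremental, n)
        rows.append(
            YearlyBudgetRow(
                year=year,
                n=n,
                arm_costs=arm_costs,
                projected_total=projected_total,
                baseline_total=baseline_total,
                incremental=incremental,
                per_patient=per_patient,
                affordability=assess_affordability(per_patient, spec.threshold),
            )
        )
    return BudgetImpactResult(
        rows=rows, cumulative=cumulative_impact(rows), spec_digest=spec_digest(spec)
    )
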