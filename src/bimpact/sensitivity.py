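"""One-way (deterministic) sensitivity analysis.

One parameter is perturbed at a time, the budget engine is re-run, and the
(axis × level) grid of outcomes is collected for spider-plot export.  Two
perturbation kinds are supported:

``multiplicative_factor``
    Multiplies the selected arms' unit costs by (1 + level) in the chosen
    scenario scope (projected, baseline, or both).  Level −0.10 is a 10%
    price cut.

``additive_percentage_points``
    Shifts the intervention uptake trajectory by a fixed number of
    percentage points in every year (level 0.10 = +10 pp), the comparator
    arms absorbing the complement in proportion to their shares.  With a
    comparator-only baseline this makes the incremental impact exactly
    affine in the shift.

Probabilistic sensitivity analysis is deliberately out of scope: budget
impact models are deterministic, and scenario/one-way analyses are the
recommended way to express their uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .engine import BudgetImpactResult, run_budget_impact
from .model import ModelSpec

_CLIP_TOL = 1e-9


class PerturbationError(ValueError):
    """A perturbation produced an infeasible spec."""


class SensitivityAxis(BaseModel):
    """One parameter to vary, and the levels to vary it over."""

    model_config = ConfigDict(extra="forbid")

    axis_id: str = Field(min_length=1)
    target: Literal["arm_unit_cost", "uptake_trajectory"]
    arm_selector: Optional[List[str]] = None
    scenario_scope: Literal["projected_only", "baseline_only", "both"] = "both"
    perturbation_kind: Literal["multiplicative_factor", "additive_percentage_points"]
    levels: List[float] = Field(min_length=1)


def _selected_arms(spec: ModelSpec, axis: SensitivityAxis) -> List[str]:
    if axis.arm_selector:
        known = set(spec.arm_ids())
        missing = [a for a in axis.arm_selector if a not in known]
        if missing:
            raise PerturbationError(
                f"axis {axis.axis_id!r} selects unknown arms {missing}"
            )
        return list(axis.arm_selector)
    if axis.target == "uptake_trajectory":
        return spec.intervention_arm_ids()
    return spec.arm_ids()


def _perturb_costs(spec: ModelSpec, axis: SensitivityAxis, level: float) -> ModelSpec:
    out = spec.model_copy(deep=True)
    arms = set(_selected_arms(spec, axis))
    factor = 1.0 + level
    if factor <= 0:
        raise PerturbationError(
            f"axis {axis.axis_id!r} level {level} drives costs non-positive"
        )
    scopes = {
        "projected_only": ("projected",),
        "baseline_only": ("baseline",),
        "both": ("projected", "baseline"),
    }[axis.scenario_scope]
    if "baseline" in scopes and out.baseline_unit_costs is None:
        # materialize so the baseline scope can diverge from the projected one
        out.baseline_unit_costs = out.unit_costs.model_copy(deep=True)
    for scope in scopes:
        table = out.unit_costs if scope == "projected" else out.baseline_unit_costs
        for arm_id in arms:
            for year in table.entries.get(arm_id, {}):
                table.entries[arm_id][year] *= factor
    return out


def _perturb_uptake(spec: ModelSpec, axis: SensitivityAxis, level: float) -> ModelSpec:
    out = spec.model_copy(deep=True)
    targets = _selected_arms(spec, axis)
    if not targets:
        raise PerturbationError(
            f"axis {axis.axis_id!r}: no intervention arm to perturb"
        )
    per_arm = level / len(targets)
    for year, shares in out.projected.shares.items():
        new = dict(shares)
        moved = 0.0
        for arm_id in targets:
            raw = new.get(arm_id, 0.0) + per_arm
            if raw < -_CLIP_TOL or raw > 1.0 + _CLIP_TOL:
                raise PerturbationError(
                    f"axis {axis.axis_id!r} level {level} drives arm {arm_id!r} "
                    f"share to {raw} in year {year}"
                )
            clipped = min(max(raw, 0.0), 1.0)
            moved += clipped - new.get(arm_id, 0.0)
            new[arm_id] = clipped
        others = [a for a in new if a not in targets]
        other_sum = sum(new[a] for a in others)
        if others and other_sum > 0:
            for a in others:
                raw = new[a] - moved * new[a] / other_sum
                if raw < -_CLIP_TOL:
                    raise PerturbationError(
                        f"axis {axis.axis_id!r} level {level} drives arm {a!r} "
                        f"share to {raw} in year {year}"
                    )
                new[a] = min(max(raw, 0.0), 1.0)
        total = sum(new.values())
        if abs(total - 1.0) > 1e-6:
            raise PerturbationError(
                f"axis {axis.axis_id!r} level {level}: year {year} shares "
                f"sum to {total} after perturbation"
            )
        if abs(total - 1.0) > 1e-12:  # renormalize only float dust
            new = {a: s / total for a, s in new.items()}
        out.projected.shares[year] = new
    return out


def perturb_spec(spec: ModelSpec, axis: SensitivityAxis, level: float) -> ModelSpec:
    """Return a perturbed deep copy of ``spec``; the original is untouched."""
    if axis.perturbation_kind == "multiplicative_factor":
        return _perturb_costs(spec, axis, level)
    return _perturb_uptake(spec, axis, level)


@dataclass(frozen=True)
class SpiderDataset:
    """Budget impacts over an (axis × level) grid, plus the base case."""

    base: BudgetImpactResult
    results: Dict[Tuple[str, float], BudgetImpactResult] = field(default_factory=dict)

    def result(self, axis_id: str, level: float) -> BudgetImpactResult:
        return self.results[(axis_id, level)]

    def axis_ids(self) -> List[str]:
        return sorted({axis_id for axis_id, _ in self.results})


def one_way_analysis(
    spec: ModelSpec, axes: Sequence[SensitivityAxis]
) -> SpiderDataset:
    """Evaluate every axis × level on a fresh copy of the spec."""
    if not axes:
        raise ValueError("at least one sensitivity axis is required")
    base = run_budget_impact(spec)
    results: Dict[Tuple[str, float], BudgetImpactResult] = {}
    for axis in axes:
        for level in axis.levels:
            results[(axis.axis_id, float(level))] = run_budget_impact(
                perturb_spec(spec, axis, level)
            )
    return SpiderDataset(base=base, results=results)


def spider_series(
    dataset: SpiderDataset,
    outcome: Literal["cumulative", "by_year"] = "cumulative",
) -> pd.DataFrame:
    """Long-format (axis_id, level, year, value_qar) table for plotting.

    The unperturbed base case appears once per axis at level 0; the
    ``year`` column holds ``"cumulative"`` for the cumulative outcome.
    """
    if outcome not in ("cumulative", "by_year"):
        raise ValueError(f"unknown outcome {outcome!r}")
    records: List[dict] = []

    def emit(axis_id: str, level: float, result: BudgetImpactResult) -> None:
        if outcome == "cumulative":
            records.append(
                {
                    "axis_id": axis_id,
                    "level": level,
                    "year": "cumulative",
                    "value_qar": result.cumulative,
                }
            )
        else:
            for row in result.rows:
                records.append(
                    {
                        "axis_id": axis_id,
                        "level": level,
                        "year": row.year,
                        "value_qar": row.incremental,
                    }
                )

    for axis_id in dataset.axis_ids():
        if (axis_id, 0.0) not in dataset.results:
            emit(axis_id, 0.0, dataset.base)
        for (aid, level), result in dataset.results.items():
            if aid == axis_id:
                emit(axis_id, level, result)
    frame = pd.DataFrame(records, columns=["axis_id", "level", "year", "value_qar"])
    return frame.sort_values(["axis_id", "level", "year"]).reset_index(drop=True)
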