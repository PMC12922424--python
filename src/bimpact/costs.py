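"""Per-patient annual cost assembly and blending.

Two ways to obtain an arm's per-patient annual cost: directly from a
:class:`~bimpact.model.UnitCostTable`, or bottom-up from itemised
components (drug acquisition per cycle plus annual laboratory, imaging,
cardiac monitoring, outpatient-visit and hospitalisation costs).
Blended costs over an arm mixture support pricing a comparator basket at
one weighted rate.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping

import pandas as pd

from .model import CostBreakdown, UnitCostTable

_WEIGHT_SUM_TOL = 1e-9


def annual_cost_from_components(breakdown: CostBreakdown) -> float:
    """Sum the bottom-up components into QAR per patient per year."""
    return (
        breakdown.drug_cost_per_cycle * breakdown.cycles_per_year
        + breakdown.lab_cost_per_year
        + breakdown.imaging_cost_per_year
        + breakdown.cardiac_monitoring_per_year
        + breakdown.outpatient_visit_cost_per_year
        + breakdown.hospitalisation_cost_per_year
    )


def blended_unit_cost(
    weights: Mapping[str, float], costs: Mapping[str, float]
) -> float:
    """Weighted mean cost over arms; weights must sum to 1."""
    total_weight = sum(weights.values())
    if not math.isclose(total_weight, 1.0, rel_tol=0, abs_tol=_WEIGHT_SUM_TOL):
        raise ValueError(f"weights sum to {total_weight!r}, expected 1")
    return sum(w * costs[arm_id] for arm_id, w in weights.items())


def unit_cost(table: UnitCostTable, arm_id: str, year: int) -> float:
    """Stored cost for (arm, year); KeyError naming both if absent."""
    return table.cost(arm_id, year)


def unit_cost_table_to_frame(table: UnitCostTable) -> pd.DataFrame:
    """Export as long-format (arm_id, year, cost_qar), sorted."""
    records = [
        {"arm_id": arm_id, "year": year, "cost_qar": cost}
        for arm_id, by_year in table.entries.items()
        for year, cost in by_year.items()
    ]
    return (
        pd.DataFrame(records, columns=["arm_id", "year", "cost_qar"])
        .sort_values(["arm_id", "year"])
        .reset_index(drop=True)
    )


def unit_cost_table_from_frame(frame: pd.DataFrame) -> UnitCostTable:
    """Inverse of :func:`unit_cost_table_to_frame`."""
    entries: Dict[str, Dict[int, float]] = {}
    for row in frame.itertuples(index=False):
        entries.setdefault(str(row.arm_id), {})[int(row.year)] = float(row.cost_qar)
    return UnitCostTable(entries=entries)
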