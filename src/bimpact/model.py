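"""Declarative model specification for a budget impact analysis.

A :class:`ModelSpec` fully describes one budget impact analysis (BIA): the
eligible population and its net growth, the treatment arms, per-patient
annual unit costs for each arm and calendar year, baseline and projected
market-share trajectories, the affordability threshold, and currency
settings.  Specs are plain data — every computation lives in the other
modules — and can be round-tripped through YAML or JSON.

Field-level constraints (types, positivity) are enforced by pydantic at
construction time.  Cross-field invariants — shares summing to one, cost
coverage, arm references — are checked by :func:`validate_model_spec`,
which *reports* violations rather than raising, so that a spec can be
inspected wholesale; :func:`load_model_spec` raises if any violation is
found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1

#: Shares in a single year must sum to 1 within this tolerance.
SHARE_SUM_TOL = 1e-9


class SpecError(ValueError):
    """A model specification failed validation."""


class TreatmentArm(BaseModel):
    """One cost-bearing treatment basket.

    An arm is opaque: it may be a single drug regimen or a blended mix of
    several (a ``comparator_mix``, e.g. "palbociclib/ribociclib/other
    standard care" priced at a single weighted per-patient rate).
    """

    model_config = ConfigDict(extra="forbid")

    arm_id: str = Field(min_length=1)
    label: str = Field(min_length=1)
    role: Literal["intervention", "comparator_mix"]


class UnitCostTable(BaseModel):
    """Per-patient annual costs keyed by arm and calendar year (QAR/patient/year).

    Costs are stored per (arm, year) rather than as a base price plus an
    inflation rule, because real price schedules drift non-uniformly.
    """

    model_config = ConfigDict(extra="forbid")

    entries: Dict[str, Dict[int, float]] = Field(default_factory=dict)

    def cost(self, arm_id: str, year: int) -> float:
        """Look up one cost; raise naming the missing arm/year."""
        try:
            return self.entries[arm_id][year]
        except KeyError:
            raise KeyError(
                f"no unit cost for arm {arm_id!r} in year {year}"
            ) from None

    def has(self, arm_id: str, year: int) -> bool:
        return year in self.entries.get(arm_id, {})


class CostBreakdown(BaseModel):
    """Bottom-up components of one arm's per-patient annual cost.

    Drug acquisition is priced per treatment cycle (28-day cycles give 13
    cycles per year); every other component is already an annual figure.
    """

    model_config = ConfigDict(extra="forbid")

    drug_cost_per_cycle: float = Field(ge=0)
    cycles_per_year: float = Field(ge=0, default=13)
    lab_cost_per_year: float = Field(ge=0, default=0.0)
    imaging_cost_per_year: float = Field(ge=0, default=0.0)
    cardiac_monitoring_per_year: float = Field(ge=0, default=0.0)
    outpatient_visit_cost_per_year: float = Field(ge=0, default=0.0)
    hospitalisation_cost_per_year: float = Field(ge=0, default=0.0)

    @model_validator(mode="after")
    def _at_least_one_positive(self) -> "CostBreakdown":
        total = (
            self.drug_cost_per_cycle * self.cycles_per_year
            + self.lab_cost_per_year
            + self.imaging_cost_per_year
            + self.cardiac_monitoring_per_year
            + self.outpatient_visit_cost_per_year
            + self.hospitalisation_cost_per_year
        )
        if total <= 0:
            raise ValueError("at least one cost component must be positive")
        return self


class PopulationModel(BaseModel):
    """Eligible cohort size and its net annual growth.

    Net growth is additive: ``incidence_rate - dropout_rate`` per year,
    compounded on the (optionally rounded) previous year's count.
    """

    model_config = ConfigDict(extra="forbid")

    base_year: int
    base_count: int = Field(gt=0)
    incidence_rate: float = Field(ge=0, le=1)
    dropout_rate: float = Field(ge=0, le=1)
    horizon_years: int = Field(ge=1, le=50)
    rounding_policy: Literal["nearest_half_away_from_zero", "none"] = (
        "nearest_half_away_from_zero"
    )

    @model_validator(mode="after")
    def _net_growth_bounded(self) -> "PopulationModel":
        if self.incidence_rate - self.dropout_rate < -1:
            raise ValueError("net growth below -100%/year")
        return self

    @property
    def years(self) -> List[int]:
        return list(range(self.base_year, self.base_year + self.horizon_years))


class MarketShareTrajectory(BaseModel):
    """Per-year arm shares for a named scenario; each year sums to 1."""

    model_config = ConfigDict(extra="forbid")

    scenario_name: str
    shares: Dict[int, Dict[str, float]]

    def years(self) -> List[int]:
        return sorted(self.shares)


class AffordabilityThreshold(BaseModel):
    """Maximum acceptable per-patient per-year incremental cost.

    The effective threshold is ``multiplier × gdp_per_capita`` unless
    ``override_value`` is given, which then wins verbatim.  Per-patient
    impacts above the threshold but within ``tolerance_fraction`` of it
    are classified "borderline" rather than "unacceptable".
    """

    model_config = ConfigDict(extra="forbid")

    gdp_per_capita: float = Field(gt=0)
    multiplier: float = Field(gt=0, default=1.5)
    override_value: Optional[float] = Field(gt=0, default=None)
    tolerance_fraction: float = Field(ge=0, default=0.10)

    @property
    def effective(self) -> float:
        if self.override_value is not None:
            return self.override_value
        return self.multiplier * self.gdp_per_capita


class CurrencySettings(BaseModel):
    """Reporting currency and the fixed USD exchange rate."""

    model_config = ConfigDict(extra="forbid")

    reporting_currency: str = "QAR"
    usd_per_unit_rate: float = Field(gt=0, default=3.65)
    conversion_rounding: Literal["truncate_toward_zero", "nearest"] = (
        "truncate_toward_zero"
    )


class ModelSpec(BaseModel):
    """Everything one budget impact run needs.

    ``unit_costs`` prices the projected scenario.  ``baseline_unit_costs``,
    when present, prices the baseline scenario instead of falling back to
    ``unit_costs``; this lets the baseline's blended "current mix" rate
    differ from the same arm's rate inside the projected mix, and gives
    sensitivity cost perturbations a per-scenario scope.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    population: PopulationModel
    arms: List[TreatmentArm]
    unit_costs: UnitCostTable
    baseline_unit_costs: Optional[UnitCostTable] = None
    baseline: MarketShareTrajectory
    projected: MarketShareTrajectory
    threshold: AffordabilityThreshold
    currency: CurrencySettings = CurrencySettings()

    def arm_ids(self) -> List[str]:
        return [a.arm_id for a in self.arms]

    def arm(self, arm_id: str) -> TreatmentArm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(f"no arm {arm_id!r}")

    def intervention_arm_ids(self) -> List[str]:
        return [a.arm_id for a in self.arms if a.role == "intervention"]

    def cost_table(self, scenario: Literal["baseline", "projected"]) -> UnitCostTable:
        if scenario == "baseline" and self.baseline_unit_costs is not None:
            return self.baseline_unit_costs
        return self.unit_costs

    def to_dict(self) -> dict:
        return self.model_dump(exclude_none=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class Violation:
    """One invariant breach found in a spec."""

    type_name: str
    field: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.type_name}.{self.field} @ {self.location}: {self.message}"


def validate_model_spec(spec: ModelSpec) -> List[Violation]:
    """Check every cross-field invariant; return violations, never raise.

    Covered: unique arm ids; trajectory shares in [0,1] summing to 1 per
    year; trajectories referencing only defined arms; baseline and
    projected covering exactly the population's year range; every
    (arm, year) with positive share having a strictly positive unit cost.
    """
    out: List[Violation] = []

    seen: set = set()
    for arm in spec.arms:
        if arm.arm_id in seen:
            out.append(
                Violation("TreatmentArm", "arm_id", arm.arm_id, "duplicate arm_id")
            )
        seen.add(arm.arm_id)

    expected_years = set(spec.population.years)
    for traj in (spec.baseline, spec.projected):
        name = traj.scenario_name
        got_years = set(traj.shares)
        for year in sorted(expected_years - got_years):
            out.append(
                Violation(
                    "MarketShareTrajectory",
                    "shares",
                    f"{name}/{year}",
                    f"scenario {name!r} missing year {year}",
                )
            )
        for year in sorted(got_years - expected_years):
            out.append(
                Violation(
                    "MarketShareTrajectory",
                    "shares",
                    f"{name}/{year}",
                    f"scenario {name!r} has year {year} outside the population horizon",
                )
            )
        for year in sorted(got_years):
            year_shares = traj.shares[year]
            for arm_id, share in year_shares.items():
                if arm_id not in seen:
                    out.append(
                        Violation(
                            "MarketShareTrajectory",
                            "shares",
                            f"{name}/{year}/{arm_id}",
                            f"unknown arm {arm_id!r}",
                        )
                    )
                if not 0.0 <= share <= 1.0:
                    out.append(
                        Violation(
                            "MarketShareTrajectory",
                            "shares",
                            f"{name}/{year}/{arm_id}",
                            f"share {share} outside [0, 1]",
                        )
                    )
            total = sum(year_shares.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=SHARE_SUM_TOL):
                out.append(
                    Violation(
                        "MarketShareTrajectory",
                        "shares",
                        f"{name}/{year}",
                        f"shares sum to {total!r} in year {year}, expected 1",
                    )
                )

    for table_name, table, traj in (
        ("unit_costs", spec.unit_costs, spec.projected),
        ("baseline_unit_costs", spec.cost_table("baseline"), spec.baseline),
    ):
        for arm_id, by_year in table.entries.items():
            for year, cost in by_year.items():
                if not cost > 0:
                    out.append(
                        Violation(
                            "UnitCostTable",
                            table_name,
                            f"{arm_id}/{year}",
                            f"cost {cost} not strictly positive",
                        )
                    )
        for year, year_shares in traj.shares.items():
            for arm_id, share in year_shares.items():
                if share > 0 and arm_id in seen and not table.has(arm_id, year):
                    out.append(
                        Violation(
                            "UnitCostTable",
                            table_name,
                            f"{arm_id}/{year}",
                            f"missing unit cost for arm {arm_id!r}, year {year} "
                            f"(share {share} in scenario {traj.scenario_name!r})",
                        )
                    )

    return out


def load_model_spec(source: str) -> ModelSpec:
    """Parse a YAML (or JSON — a YAML subset) document into a validated spec.

    Raises :class:`SpecError` naming the offending field and year on any
    schema or invariant violation.
    """
    try:
        raw = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        raise SpecError(f"specification is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SpecError("specification document must be a mapping")
    try:
        spec = ModelSpec.model_validate(raw)
    except Exception as exc:
        raise SpecError(f"specification schema violation: {exc}") from exc
    violations = validate_model_spec(spec)
    if violations:
        detail = "; ".join(str(v) for v in violations)
        raise SpecError(f"specification invalid: {detail}")
    return spec


def load_model_spec_file(path) -> ModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return load_model_spec(fh.read())


def convert_currency(amount: float, settings: CurrencySettings) -> int:
    """Convert a QAR amount to whole USD at the spec's fixed rate.

    ``truncate_toward_zero`` drops the fractional dollar (14,001,749 QAR at
    3.65 → 3,836,095 USD); ``nearest`` rounds half away from zero.
    """
    if not math.isfinite(amount):
        raise ValueError(f"cannot convert non-finite amount {amount!r}")
    usd = amount / settings.usd_per_unit_rate
    if settings.conversion_rounding == "truncate_toward_zero":
        return math.trunc(usd)
    return int(math.floor(usd + 0.5)) if usd >= 0 else int(math.ceil(usd - 0.5))
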