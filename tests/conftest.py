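import pytest

from bimpact import (
    AffordabilityThreshold,
    CurrencySettings,
    MarketShareTrajectory,
    ModelSpec,
    PopulationModel,
    TreatmentArm,
    UnitCostTable,
    load_printed_rows,
    scenario1_fixture,
    scenario2_fixture,
)


@pytest.fixture(scope="session")
def scenario1_spec():
    return scenario1_fixture()


@pytest.fixture(scope="session")
def scenario2_spec():
    return scenario2_fixture()


@pytest.fixture(scope="session")
def scenario1_rows():
    return load_printed_rows("scenario1")


@pytest.fixture(scope="session")
def scenario2_rows():
    return load_printed_rows("scenario2")


def make_two_arm_spec(
    *,
    base_count=100,
    incidence=0.05,
    dropout=0.0,
    horizon=3,
    cost_new=100.0,
    cost_old=200.0,
    uptake=(0.2, 0.4, 0.6),
    baseline_uptake=None,
    base_year=2024,
):
    """Small hand-built two-arm spec used across the engine/sensitivity tests."""
    years = range(base_year, base_year + horizon)
    cost_new = dict(zip(years, [cost_new] * horizon)) if isinstance(cost_new, (int, float)) else cost_new
    cost_old = dict(zip(years, [cost_old] * horizon)) if isinstance(cost_old, (int, float)) else cost_old
    baseline_uptake = baseline_uptake or [0.0] * horizon
    return ModelSpec(
        population=PopulationModel(
            base_year=base_year,
            base_count=base_count,
            incidence_rate=incidence,
            dropout_rate=dropout,
            horizon_years=horizon,
        ),
        arms=[
            TreatmentArm(arm_id="new", label="New therapy", role="intervention"),
            TreatmentArm(arm_id="old", label="Standard mix", role="comparator_mix"),
        ],
        unit_costs=UnitCostTable(
            entries={"new": dict(cost_new), "old": dict(cost_old)}
        ),
        baseline=MarketShareTrajectory(
            scenario_name="baseline",
            shares={
                y: {"new": s, "old": 1.0 - s}
                for y, s in zip(years, baseline_uptake)
            },
        ),
        projected=MarketShareTrajectory(
            scenario_name="projected",
            shares={y: {"new": s, "old": 1.0 - s} for y, s in zip(years, uptake)},
        ),
        threshold=AffordabilityThreshold(gdp_per_capita=300_000.0),
        currency=CurrencySettings(),
    )


@pytest.fixture
def two_arm_spec():
    return make_two_arm_spec()
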