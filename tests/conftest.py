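import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from azollatpc import (
    FitConfig,
    GrowthRecord,
    RecordTable,
    RoomParams,
    SimulationSpec,
    VarianceComponents,
    simulate_records,
)
from azollatpc.simulate import PINNATA_REFERENCE


@pytest.fixture
def pinnata_params() -> RoomParams:
    """Reference curve for the heat-tolerant species."""
    return PINNATA_REFERENCE


@pytest.fixture
def small_table() -> RecordTable:
    """Two studies, three records each, spanning both sides of the optimum."""
    rows = [
        ("s1", 15.0, 0.06),
        ("s1", 24.5, 0.26),
        ("s1", 35.0, 0.17),
        ("s2", 18.0, 0.10),
        ("s2", 25.0, 0.22),
        ("s2", 33.0, 0.15),
    ]
    return RecordTable(
        records=[
            GrowthRecord(sid, "A_pinnata", t, y, "reported") for sid, t, y in rows
        ]
    )


@pytest.fixture
def variance() -> VarianceComponents:
    return VarianceComponents(sigma_resid=0.03, sigma_study=0.2)


@pytest.fixture
def simulated_table() -> RecordTable:
    return simulate_records(SimulationSpec(seed=11))


@pytest.fixture
def fast_fit_config() -> FitConfig:
    return FitConfig(seed=0, n_starts=4)
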