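import numpy as np
import pytest

from strokecea import (
    LifeTable,
    ParameterSet,
    RunConfig,
    generate_life_table,
    generate_parameter_table,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return generate_parameter_table()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return generate_life_table()


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def fresh_params() -> ParameterSet:
    """Mutable copy for tests that perturb parameters."""
    return generate_parameter_table()


def single_state_params(
    utility: float = 0.8,
    p_death: float = 0.2,
    state: int = 2,
) -> tuple[ParameterSet, LifeTable]:
    """Degenerate setup: all 90-day mass on one living state, constant
    annual death probability, no recurrence — the closed-form testbed."""
    ps = generate_parameter_table()
    for arm in ps.mrs90_dist:
        v = np.zeros(7)
        v[state] = 1.0
        ps.mrs90_dist[arm] = v
    ps.utility = np.full(6, utility)
    ps.p_recurrent_annual = 0.0
    ps.mortality_hr = np.ones(6)
    # flat-hazard life table long enough for series convergence
    n = 1100
    qx = np.full(n, p_death)
    qx[-1] = 1.0
    ages = np.arange(int(ps.start_age), int(ps.start_age) + n)
    return ps, LifeTable(ages, qx)
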