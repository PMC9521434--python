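"""Shared fixtures.

The full-scale dimensional sweeps (9 levels x 1,000 iterations x 10 seeds) are
session-scoped: several acceptance checks read different quantities off the
same tables.
"""

import pytest

from damsim import SimulationConfig
from damsim.experiments import sweep


@pytest.fixture(scope="session")
def avoidance_sweep():
    return sweep("avoidance", n_seeds=10)


@pytest.fixture(scope="session")
def ambivalence_sweep():
    return sweep("ambivalence", n_seeds=10)


@pytest.fixture(scope="session")
def variable_c0_sweep():
    base = SimulationConfig(dimension="avoidance")
    var = base.model_copy(
        update={"consts": base.consts.model_copy(update={"variable_c0": True})}
    )
    return sweep("avoidance", n_seeds=10, base_config=var)


@pytest.fixture()
def default_config():
    return SimulationConfig()
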