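import numpy as np
import pytest

from torquesim import fixtures
from torquesim.config import SimulationConfig


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def pool(default_config):
    return fixtures.default_pool(default_config)


@pytest.fixture(scope="session")
def arch(default_config):
    from torquesim.hill_muscle import MuscleArchitecture

    return MuscleArchitecture.from_config(default_config.muscle)


@pytest.fixture(scope="session")
def met_consts(default_config):
    from torquesim.bioenergetics import MetabolicConstants

    return MetabolicConstants.from_config(default_config.metabolic)


@pytest.fixture(scope="session")
def joint_params(default_config, pool):
    from torquesim.joint_mechanics import JointParams

    return JointParams.from_config(default_config.joint, float(pool.fmax_n.sum()))
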