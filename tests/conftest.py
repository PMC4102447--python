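import numpy as np
import pytest

from bindfe import SimulationConditions


@pytest.fixture(scope="session")
def conditions() -> SimulationConditions:
    return SimulationConditions()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140717)
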