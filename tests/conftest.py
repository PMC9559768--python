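import numpy as np
import pytest

import floodaccess as fa
from floodaccess.synthetic import SMALL_EXTENT, small_config


@pytest.fixture(scope="session")
def small_scenario():
    return fa.preset_scenario("small", 1)


@pytest.fixture(scope="session")
def bridge():
    return fa.bridge_scenario()


@pytest.fixture(scope="session")
def small_scenarios():
    """A handful of seeded small scenarios for property sweeps."""
    return [fa.generate_scenario(s, small_config(), SMALL_EXTENT) for s in range(1, 11)]


@pytest.fixture
def uniform_friction():
    """10x12 obstacle-free friction grid at a constant 0.02 min/m."""
    frame = fa.GridFrame(0.0, 1000.0, 100.0, 10, 12)
    return fa.FrictionGrid(frame, np.full((10, 12), 0.02))
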