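import warnings

import numpy as np
import pytest

from understory_hsm import RunConfig
from understory_hsm import synth

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_scene():
    """A 3 x 3 km scene with a handful of settlements, shared across tests."""
    scene = synth.generate_landscape(
        (3000.0, 3000.0), seed=7, settlement_intensity=1.0
    )
    assert len(scene.settlements) > 0
    return scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
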