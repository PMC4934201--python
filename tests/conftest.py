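import numpy as np
import pytest

from canopysif.forward import CanopyScene
from canopysif.pipeline import simulate_observation
from canopysif.spectra import uniform_grid


@pytest.fixture(scope="session")
def ref_scene():
    """Reference vegetated scene: Cab 40, LAI 4, 30 degree sun."""
    return CanopyScene.from_conditions(40.0, 4.0, 30.0)


@pytest.fixture(scope="session")
def ref_obs(ref_scene):
    """Noiseless instrument-grid observation of the reference scene."""
    return simulate_observation(ref_scene)


@pytest.fixture(scope="session")
def o2a_grid():
    """Fine grid around O2-A whose samples hit the table anchors exactly."""
    return uniform_grid(750.519, 775.519, 0.05)
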