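import numpy as np
import pytest

from mitralflow import BeatSpec, FlowSpec, FluidProps


@pytest.fixture
def fluid():
    """Water/glycerol blood analogue: 4.2 cP, 1100 kg/m^3."""
    return FluidProps()


@pytest.fixture
def rest_beat():
    return BeatSpec.rest()


@pytest.fixture
def exercise_beat():
    return BeatSpec.exercise()


@pytest.fixture
def jet_spec():
    """Transmitral jet on an 8 cm square grid, 1.25 mm node spacing."""
    return FlowSpec(model="transmitral_jet", params={"width": 0.024},
                    grid_shape=(64, 64), grid_spacing=1.25e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
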