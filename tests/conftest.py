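import numpy as np
import pytest

from occgray import DWCAParams, PlateSpec, make_plate, make_warm_cool_card


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture(scope="session")
def random_image(rng):
    """Small random RGB image (8x8) for metric oracles."""
    return rng.random((8, 8, 3))


@pytest.fixture(scope="session")
def default_params():
    return DWCAParams()


@pytest.fixture(scope="session")
def card():
    """Luma-matched warm/cool card plus its region masks."""
    return make_warm_cool_card()


@pytest.fixture(scope="session")
def small_plate():
    """One small luma-matched plate shared across plate tests."""
    return make_plate(PlateSpec(size=128, seed=7))
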