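import numpy as np
import pytest

from saslepr import FieldGrid, FastMotionParams, simulate_fast_motion


@pytest.fixture(scope="session")
def grid4096():
    return FieldGrid.default(4096)


@pytest.fixture(scope="session")
def grid2048():
    return FieldGrid.default(2048)


@pytest.fixture(scope="session")
def asymmetric_fast_params():
    """A Lorentzian triplet with mI-dependent broadening (nonzero B and C)."""
    return FastMotionParams(width_A=0.15, width_B=-0.02, width_C=0.03)


@pytest.fixture(scope="session")
def asymmetric_fast_spectrum(asymmetric_fast_params, grid4096):
    return simulate_fast_motion(asymmetric_fast_params, grid4096)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
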