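import numpy as np
import pytest

from texkem.projector import SystemModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    """32-pixel grid with proportionally scaled sinogram (cheap to build)."""
    return SystemModel(32, n_radial=46, n_angles=31)


@pytest.fixture(scope="session")
def full_model():
    """The reference 217-pixel grid with its 249 x 210 sinogram."""
    return SystemModel(217)
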