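import numpy as np
import pytest

from retinal_contrast.gsf import Geometry, GlareParameters
from retinal_contrast.targets import TargetSpec, generate_target


@pytest.fixture(scope="session")
def default_params():
    return GlareParameters(age_years=25.0, pigment=0.5)


@pytest.fixture(scope="session")
def small_geometry():
    return Geometry(width_px=5, height_px=5)


@pytest.fixture(scope="session")
def half_target_small():
    """A small 50%-White double-density target shared across tests."""
    return generate_target(TargetSpec(background="half", width_px=96, height_px=80,
                                      n_test_pairs=4, test_square_px=8,
                                      mosaic_sizes=(1, 2, 4, 8), seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
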