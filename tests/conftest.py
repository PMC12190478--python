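import numpy as np
import pytest

from scorimap import make_grid
from scorimap.field_stimuli import ApertureSpec
from scorimap.rf_models import DoGParams


@pytest.fixture(scope="session")
def grid():
    """The default 200 x 200 pixel grid over +/-60 deg."""
    return make_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A cheap 40 x 40 grid over +/-12 deg for brute-force comparisons."""
    return make_grid(12.0, 40)


@pytest.fixture(scope="session")
def sf_family():
    """Center-surround family preferring 0.08 cycles/deg."""
    return DoGParams(sigma_center=0.8, sigma_surround=4.7, cs_ratio=0.4)


@pytest.fixture(scope="session")
def aperture_family():
    """Center-surround family preferring 0.04 cycles/deg."""
    return DoGParams(sigma_center=1.5, sigma_surround=11.4, cs_ratio=0.8)


@pytest.fixture(scope="session")
def circle30():
    return ApertureSpec("circle", 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
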