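import numpy as np
import pytest

from kvtrack.geometry import ImagingGeometry
from kvtrack.phantom import PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def small_geometry():
    """64 px / 5 mm geometry covering the same 320 mm field of view."""
    return ImagingGeometry(image_size=64, pixel_spacing=5.0)


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(shape=(64, 64, 64), spacing=5.0, n_fiducials=0)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return build_phantom(small_phantom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
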