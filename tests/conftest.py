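import numpy as np
import pytest

from chromascene.colorimetry import DEFAULT_WAVELENGTHS, IlluminantSpectrum
from chromascene.synthetic import SceneConfig, generate_reflectance_cube


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    return SceneConfig(width=48, height=48, seed=7)


@pytest.fixture
def flat_illuminant():
    """Equal-energy illuminant of unit power on the native grid."""
    return IlluminantSpectrum(DEFAULT_WAVELENGTHS, np.ones(DEFAULT_WAVELENGTHS.size))


@pytest.fixture
def reflectance(small_config):
    return generate_reflectance_cube(small_config)
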