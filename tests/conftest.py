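import numpy as np
import pytest

from simsect import (
    GridFrequency,
    IlluminationPattern,
    OpticalConfig,
    SceneSpec,
    render_triplet,
)

#: The instrument's discrete grid frequencies with the 4x NA 0.1 objective.
TABLE1_4X = (101.0, 67.0, 50.3, 47.7, 40.7, 31.7, 24.1, 19.6)


@pytest.fixture(scope="session")
def config():
    """4x NA 0.1 objective, 520 nm emission, 1.5 um pixels."""
    return OpticalConfig(na=0.1, wavelength_em=520.0, magnification=4.0,
                         pixel_size=1.5)


@pytest.fixture(scope="session")
def operating_frequency(config):
    """The selected operating grid frequency, 31.7 mm^-1."""
    return GridFrequency.from_absolute(31.7, config)


@pytest.fixture
def pattern(operating_frequency):
    return IlluminationPattern(m0=0.8, nu=operating_frequency)


@pytest.fixture
def flat_scene():
    """Uniform in-focus layer over uniform background, non-scattering."""
    return SceneSpec(
        focal_map=np.full((16, 64), 2.0),
        background_map=np.full((16, 64), 5.0),
        mus_prime=0.0,
    )


@pytest.fixture
def flat_triplet(flat_scene, pattern, config):
    return render_triplet(flat_scene, pattern, config)
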