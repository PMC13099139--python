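import numpy as np
import pytest

from centroscreen import synth


@pytest.fixture(scope="session")
def default_mask():
    """Reference elliptical nucleus mask (~102 µm² at 0.108 µm/px)."""
    mask, record = synth.generate_nucleus_mask(
        synth.NucleusShapeParams(), pixel_size=0.108, field_shape=(512, 512), seed=0
    )
    return mask, record


@pytest.fixture(scope="session")
def disk_mask():
    """Circular mask of radius 40 px centred in a small field."""
    yy, xx = np.mgrid[0:96, 0:96]
    return (yy - 48.0) ** 2 + (xx - 48.0) ** 2 <= 40.0**2


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
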