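import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage as ndi

import myoseg as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ring_fixture():
    """Bright ring (inner radius 50, width 3) on flat background, 128x128."""
    n = 128
    rr, cc = np.mgrid[0:n, 0:n]
    rad = np.sqrt((rr - n // 2) ** 2 + (cc - n // 2) ** 2)
    img = np.zeros((n, n), np.uint8)
    img[(rad >= 50) & (rad < 53)] = 255
    return img, rad


@pytest.fixture(scope="session")
def dumbbell_fixture():
    """Two r=10 discs joined by a 4px-wide neck, with a 1px outline border."""
    h, w = 33, 63
    rr, cc = np.mgrid[0:h, 0:w]
    d1 = ((rr - 16) ** 2 + (cc - 16) ** 2) <= 100
    d2 = ((rr - 16) ** 2 + (cc - 46) ** 2) <= 100
    neck = (np.abs(rr - 16) <= 2) & (cc >= 16) & (cc <= 46)
    shape = d1 | d2 | neck
    border = ndi.binary_dilation(shape) & ~shape
    return border, shape


@pytest.fixture(scope="session")
def grid_border():
    """A drawn 3x3 grid of square cells: 1px borders on the grid lines."""
    n = 65
    border = np.zeros((n, n), bool)
    for line in (2, 22, 42, 62):
        border[line, 2:63] = True
        border[2:63, line] = True
    return border


@pytest.fixture(scope="session")
def clean_sample():
    return m.generate_cross_section(
        m.SyntheticConfig(seed=11, **{**dict(
            border_hole_rate=0.0, speckle_sd=0.0, gap_noise_sd=0.0,
            stitch_step=0, border_intensity=255,
            fibre_intensity_range=(60, 110))})
    )


@pytest.fixture(scope="session")
def moderate_sample():
    return m.generate_cross_section(
        m.SyntheticConfig(
            height=320, width=320, n_fibres=28, border_hole_rate=0.25,
            speckle_sd=10.0, gap_noise_sd=6.0, border_intensity=230,
            fibre_intensity_range=(50, 130), seed=3,
        )
    )


@pytest.fixture(scope="session")
def trained_classifier(moderate_sample):
    ann = m.annotation_from_groundtruth(moderate_sample, strokes_per_class=8, seed=100)
    return m.FibrePixelClassifier(random_state=0).fit(moderate_sample.image, ann)
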