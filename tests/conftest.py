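import numpy as np
import pandas as pd
import pytest

from phonescope import presets, simcam


@pytest.fixture
def smartphone_camera():
    return presets.camera("smartphone")


@pytest.fixture
def smartphone_optics():
    return presets.optics("smartphone")


@pytest.fixture
def mono_camera():
    """Noise-free mono camera: convenient for exact rendering checks."""
    return simcam.CameraModel(pixel_size_nm=430.0, bayer_pattern="mono",
                              baseline=100.0, read_noise_sd=0.0, gain=1.0,
                              channel_sensitivity={"mono": 1.0},
                              bit_depth=16, frame_time=0.25)


def make_site_layout(sites, field=(40000.0, 40000.0), design="manual"):
    """Layout from explicit (x, y, type, extent) tuples."""
    rows = [(i, i, x, y, t, e) for i, (x, y, t, e) in enumerate(sites)]
    df = pd.DataFrame(rows, columns=["structure_id", "site_id", "x_nm",
                                     "y_nm", "type", "site_extent_nm"])
    return simcam.EmitterLayout(sites=df, field_size_nm=field, design=design)


@pytest.fixture
def single_emitter_layout():
    return make_site_layout([(20000.0, 20000.0, simcam.SITE_FIDUCIAL, 0.0)])


def integrated_gaussian_roi(shape, x, y, photons, sigma, background=0.0):
    """Reference pixel-integrated Gaussian image (edge coordinates)."""
    from scipy.special import ndtr
    h, w = shape
    ex = np.diff(ndtr((np.arange(w + 1) - x) / sigma))
    ey = np.diff(ndtr((np.arange(h + 1) - y) / sigma))
    return photons * np.outer(ey, ex) + background
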