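import numpy as np
import pytest

import scintidose as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """A 10 cm cube at coarse resolution for fast end-to-end runs."""
    return sd.make_grid((20, 20, 20), 5.0)


def three_cameras(n_pix: int, pitch: float, lam: float = 0.0, **kw):
    """Three orthogonal parallel-view cameras covering the phantom."""
    return [
        sd.CameraModel(id="cam_top", view_axis="+z", pixel_shape=(n_pix, n_pix),
                       pixel_pitch=pitch, attenuation_lambda=lam, **kw),
        sd.CameraModel(id="cam_front", view_axis="-y", pixel_shape=(n_pix, n_pix),
                       pixel_pitch=pitch, attenuation_lambda=lam, **kw),
        sd.CameraModel(id="cam_side", view_axis="+x", pixel_shape=(n_pix, n_pix),
                       pixel_pitch=pitch, attenuation_lambda=lam, **kw),
    ]
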