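import numpy as np
import pytest

from hrmesim.acquisition import AcquisitionParams, Frame, FrameSequence
from hrmesim.phantom import generate_phantom


@pytest.fixture
def small_params():
    """Desk-scale acquisition: 80 px raster, linear gamma, noiseless."""
    return AcquisitionParams(
        frame_rate=70.0, exposure=1.4, pixel_pitch=1.24,
        fov_diameter=99.2, lateral_resolution=4.0,
        gamma_exponent=1.0, noise_sigma=0.0,
    )


@pytest.fixture
def dense_phantom():
    return generate_phantom(
        extent=(400.0, 400.0), nucleus_density=500.0,
        nucleus_radius_range=(3.0, 5.0), seed=11,
    )


def make_frame(pixels, params=None, gamma_encoded=True, timestamp=0.0):
    params = params or AcquisitionParams(gamma_exponent=1.0, noise_sigma=0.0)
    return Frame(pixels=np.asarray(pixels, dtype=float), params=params,
                 timestamp=timestamp, gamma_encoded=gamma_encoded)


def make_sequence(arrays, params=None, gamma_encoded=True):
    params = params or AcquisitionParams(gamma_exponent=1.0, noise_sigma=0.0)
    frames = [
        make_frame(a, params, gamma_encoded, timestamp=i * params.frame_period_ms)
        for i, a in enumerate(arrays)
    ]
    return FrameSequence(frames=frames)
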