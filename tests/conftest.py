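import numpy as np
import pytest

from swemap import MuscleConfig, ScanProtocol, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact smooth phantom shared by reconstruction-level tests."""
    return make_phantom(
        seed=11,
        length_mm=80.0,
        radius_x_mm=16.0,
        radius_y_mm=12.0,
        radial_gradient=0.3,
        angular_gradient=0.05,
        longitudinal_gradient=0.1,
        texture_amplitude=0.02,
    )


@pytest.fixture(scope="session")
def constant_phantom():
    """Uniform 1.5 m/s field, no texture: exact-value oracle for sampling."""
    return make_phantom(
        seed=5,
        length_mm=80.0,
        radius_x_mm=16.0,
        radius_y_mm=12.0,
        base_swv=1.5,
        radial_gradient=0.0,
        angular_gradient=0.0,
        longitudinal_gradient=0.0,
        texture_amplitude=0.0,
    )


@pytest.fixture
def clean_protocol():
    """Noise- and jitter-free protocol with dense lateral coverage."""
    return ScanProtocol(
        n_swipes=7,
        frame_spacing_mm=4.0,
        swipe_lateral_offset_mm=5.0,
        noise_sd_mps=0.0,
        frame_width_mm=40.0,
        frame_depth_mm=30.0,
        pixel_spacing_mm=1.0,
        lateral_wobble_mm=0.0,
    )


@pytest.fixture
def centroid_config():
    return MuscleConfig(origin_mode="centroid", n_slices=6, n_angular=6, n_radial=4)
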