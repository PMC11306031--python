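import numpy as np
import pytest

from rootqsm.pointcloud import PointCloud
from rootqsm.synth import SynthSpec, generate_root_system


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cylinder_cloud():
    """Noiseless 300-point cylinder surface: radius 0.05 m, +z axis, length 0.4 m."""
    r, length, n = 0.05, 0.4, 300
    g = np.random.default_rng(7)
    theta = g.uniform(0, 2 * np.pi, n)
    z = g.uniform(0, length, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return PointCloud(pts), r, length


@pytest.fixture
def small_spec():
    """Small synthetic root system for fast end-to-end tests (~4k points)."""
    return SynthSpec(
        taproot_length=1.0,
        taproot_basal_radius=0.035,
        n_first_order=3,
        n_second_order_per_first=1,
        point_density=1.2e4,
        noise_sigma=0.0,
        seed=5,
        name="small",
    )


@pytest.fixture
def small_root(small_spec):
    return generate_root_system(small_spec)
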