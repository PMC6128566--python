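import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_image():
    """A dark disk (0.2) on a light background (0.8), with its mask."""
    n, r = 256, 50
    yy, xx = np.mgrid[:n, :n]
    disk = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= r ** 2
    img = np.where(disk[..., None], 0.2, 0.8) * np.ones((n, n, 3))
    return img, disk


@pytest.fixture
def small_table():
    """A quick synthetic table: 40+40 rows, 30 features, 5 informative."""
    from dermdecide.synth import SyntheticTableSpec, make_feature_table

    spec = SyntheticTableSpec(seed=7, n_pos=40, n_neg=40, q=30,
                              n_informative=5, delta=2.0, block_size=6)
    return make_feature_table(spec)
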