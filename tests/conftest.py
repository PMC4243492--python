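import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stcp.hierarchy import HierarchyConfig, PoolSpec, build_hierarchy
from stcp.image import ChannelImage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 3-level 16x16 hierarchy for hand-checkable propagation."""
    return HierarchyConfig(
        input_shape=(16, 16),
        channels=("a", "b"),
        pools=(PoolSpec(2, 2), PoolSpec(2, 2)),
        central_radius_deg=10.0,
        deg_per_pixel=1.0,
    )


@pytest.fixture
def small_vh(small_config):
    return build_hierarchy(small_config)


@pytest.fixture
def default_config():
    return HierarchyConfig(input_shape=(64, 64), channels=("colorA", "colorB"))


def random_image(rng, channels=("a", "b"), shape=(16, 16), scale=1.0):
    return ChannelImage(
        tuple(channels), rng.uniform(0, scale, size=(len(channels),) + tuple(shape))
    )
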