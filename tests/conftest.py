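import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simfuse.spaces import FeatureSpace

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_space():
    """Three diseases, unsigned: d1/d2 identical, d3 disjoint."""
    return FeatureSpace(
        name="toy",
        kind="unsigned",
        members={"d1": {"fA"}, "d2": {"fA"}, "d3": {"fB"}},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
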