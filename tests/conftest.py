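import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240814)


@pytest.fixture
def two_step():
    """Reference two-stage pathway: slow primary, fast secondary mutation."""
    from symdrift import MutationPathway

    return MutationPathway(rates=(1e-6, 1e-3))
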