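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


@pytest.fixture(scope="session")
def small_net():
    from evsynth.core import make_network

    return make_network(n_x=4, n_z=5, seed=11)


@pytest.fixture(scope="session")
def default_net():
    from evsynth.core import make_network

    return make_network(seed=7)


@pytest.fixture(scope="session")
def narrow_condition():
    from evsynth.simulation import RangeCondition

    return RangeCondition()
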