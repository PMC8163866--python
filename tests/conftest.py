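import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def brain_phantom():
    from mirscan import make_brain_phantom

    return make_brain_phantom((4.0, 4.0), 20.0, seed=0)


@pytest.fixture(scope="session")
def liver_phantom():
    from mirscan import make_liver_phantom

    return make_liver_phantom((6.0, 6.0), 20.0, 3.0, 0.3, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
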