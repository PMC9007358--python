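import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from freeplay.config import RunConfig
from freeplay.simulate import default_profile, generate_session

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def short_session(profile):
    """A 5-minute hip session shared by read-only tests."""
    return generate_session("S01", "hip", 5.0, profile, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220413)


@pytest.fixture(scope="session")
def full_study():
    """The default seeded study: 31 subjects, 21/10 split, 20-min sessions.

    Expensive (a few minutes); shared across the evaluation tests.
    """
    from freeplay.study import run_study

    return run_study(RunConfig())
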