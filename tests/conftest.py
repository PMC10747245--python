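import numpy as np
import pytest

from gaitval import GaitProfile, make_trial


@pytest.fixture(scope="session")
def default_profile():
    return GaitProfile(seed=42, n_cycles=5)


@pytest.fixture(scope="session")
def noiseless_trial(default_profile):
    """Default noiseless trial: pose equals reference exactly."""
    return make_trial(default_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
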