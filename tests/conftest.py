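import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bntpet.simulate import default_study, generate_noiseless


@pytest.fixture(scope="session")
def study():
    return default_study()


@pytest.fixture(scope="session")
def noiseless(study):
    """Noiseless (target, reference) pairs for all five release conditions."""
    return {c.name: generate_noiseless(c, study) for c in study.conditions}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
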