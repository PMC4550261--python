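import numpy as np
import pytest
from hypothesis import settings as _hsettings

from pregsignal.config import StudyConfig
from pregsignal.synthetic import generate_study

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests (seed 0)."""
    return generate_study(StudyConfig(rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
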