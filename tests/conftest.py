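import numpy as np
import pytest

from hrsurvey import ScoringScheme, make_default_templates
from hrsurvey.benchmarks import seed_profile


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def templates():
    return make_default_templates(1)


@pytest.fixture(scope="session")
def hr_profile():
    """A profile built from 30 synthetic homologs with anchor weighting."""
    model, hr, hhe, decoys = seed_profile(seed=1)
    return model, hr, hhe, decoys


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
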