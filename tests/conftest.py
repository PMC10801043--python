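import numpy as np
import pytest
from hypothesis import settings

from navassess.synthetic_cohort import reference_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The frozen seed-pinned reference cohort (sessions, questionnaires)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def sessions(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def questionnaires(cohort):
    return cohort[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
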