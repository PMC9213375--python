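import numpy as np
import pytest

from mepescore.synthetic import GROUP_A_TABLES, make_fixture_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic 100-patient cohort with the exact derivation-cohort tables."""
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def group_a_tables():
    return GROUP_A_TABLES


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
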