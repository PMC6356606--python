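import numpy as np
import pytest

from plcscore import load_table2_fixture, score_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def fixture_scores(fixture_cohort):
    return score_cohort(fixture_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
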