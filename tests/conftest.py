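import numpy as np
import pytest

from datlearn import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def table1_records():
    return synthetic.load_table1()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject synthetic cohort at the default study conditions."""
    return synthetic.gen_cohort(synthetic.CohortSpec(n_subjects=40, seed=7))
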