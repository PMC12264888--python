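import numpy as np
import pytest

import lesionpls as lp


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (40 subjects, 48 regions) for fast end-to-end checks."""
    return lp.generate_cohort(lp.small_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return lp.assemble_dataset(small_cohort.modalities, small_cohort.behaviour)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale cohort at generator defaults (86 subjects, 384 regions)."""
    return lp.generate_cohort(lp.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return lp.assemble_dataset(default_cohort.modalities, default_cohort.behaviour)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
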