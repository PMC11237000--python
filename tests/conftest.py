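import numpy as np
import pytest

import chickspec as cs


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (15 + 15, Δf = 0.10)."""
    return cs.simulate_cohort(cs.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    return cs.preprocess_set(default_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no sex effect (equal oxy-fraction means)."""
    cfg = cs.CohortConfig(
        seed=11, oxy_fraction_male_mean=0.70, oxy_fraction_female_mean=0.70
    )
    return cs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def contrast():
    """Noiseless oxy-minus-deoxy pure-component difference (the planted signature)."""
    return cs.oxy_minus_deoxy_contrast()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
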