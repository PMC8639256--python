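import warnings

import numpy as np
import pytest

from copsway.features import feature_table
from copsway.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort: 6 + 5 subjects, 2 trials, 12 s trials."""
    return CohortSpec(
        n_nonfall=6, n_fall=5, trials_per_condition=2, duration=12.0, seed=101
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    dataset, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return feature_table(dataset.records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
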