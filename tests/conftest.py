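import numpy as np
import pytest

from subgroupcox import SimulationConfig, SubgroupedSurvivalData, generate_dataset


def make_random_data(n, p, seed, n_subgroups=2, censor_frac=0.4):
    """Small unstructured survival dataset for unit tests."""
    rng = np.random.default_rng(seed)
    times = rng.exponential(1.0, n) + 0.05
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    subgroups = rng.integers(1, n_subgroups + 1, n)
    # force every label to occur
    subgroups[:n_subgroups] = np.arange(1, n_subgroups + 1)
    covariates = rng.normal(size=(n, p))
    return SubgroupedSurvivalData(times, events, subgroups, covariates)


@pytest.fixture
def small_data():
    return make_random_data(n=30, p=3, seed=42)


@pytest.fixture
def four_group_data():
    """Moderate four-subgroup cohort from the study generator."""
    return generate_dataset(SimulationConfig(n_per_subgroup=30, p=12, epsilon=0.5, seed=9))
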