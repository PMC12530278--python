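import numpy as np
import pandas as pd
import pytest

from mesothresh import CountTable, SyntheticExperimentConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return CountTable(pd.DataFrame(
        [[1, 2], [0, 5], [3, 0]],
        index=["s1", "s2", "s3"], columns=["t1", "t2"]))


def random_count_table(rng, n_samples=6, n_taxa=8, max_count=50):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return CountTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)]))


@pytest.fixture
def small_experiment():
    """A down-scaled synthetic experiment for fast unit tests."""
    cfg = SyntheticExperimentConfig(
        n_taxa=60, depth_mean=4000.0, days=(10, 89), rng_seed=7)
    return generate_experiment(cfg)
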