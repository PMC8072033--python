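import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from notchdose.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-region dataset with 5 planted genes per dose class."""
    config = SimConfig(n_regions=60, seed=0, n_background_genes=200)
    return simulate_dataset(config, {"low_I": 5, "low_II": 5, "high": 5})


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study: 500 regions, 20 planted per class, 440 nulls."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def truth_by_region(dataset) -> pd.Series:
    return dataset.truth.set_index("region_id")["true_class"]


def truth_by_gene(dataset) -> pd.Series:
    return dataset.truth.set_index("gene_id")["true_class"]
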