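import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from bloodsig.io import FeatureTable, read_newick
from bloodsig.synth import GeneratorConfig, simulate_dataset

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    """Four-branch toy tree with hand-computable PD/UniFrac values."""
    return read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator: 3 studies x 8+8 samples, 60 taxa."""
    return GeneratorConfig(
        n_studies=3,
        n_control=8,
        n_case=8,
        n_taxa=60,
        n_core=8,
        n_amplified=5,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=42)


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[3, 0], [1, 2]], index=["s1", "s2"], columns=["G1", "G2"]
    )
    return FeatureTable(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
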