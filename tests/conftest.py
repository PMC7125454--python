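import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirpathnet import CountMatrix, SimulationConfig, simulate_all

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, 2 tumor / 2 control."""
    counts = pd.DataFrame(
        [[10, 12, 5, 6], [100, 90, 95, 105], [0, 1, 2, 0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    cond = pd.Series(
        ["tumor", "tumor", "control", "control"], index=counts.columns, dtype=object
    )
    return CountMatrix(counts, cond)


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulation shared across tests."""
    config = SimulationConfig(
        n_genes=400, n_mirnas=60, n_tumor=30, n_control=20,
        n_de_genes=100, n_de_mirnas=12, n_pathways=40,
        pathway_size_range=(8, 12), n_target_genes=12, seed=77,
    )
    return config, simulate_all(config)
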