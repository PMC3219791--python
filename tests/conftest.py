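import numpy as np
import pandas as pd
import pytest

import droughtseq as dq
from droughtseq.qc import CountMatrix


@pytest.fixture(scope="session")
def small_config():
    return dq.SimulationConfig(n_genes=400, seed=9)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """One small simulated experiment shared across tests (read-mostly)."""
    matrix, truth = dq.simulate_counts(small_config)
    annotations = dq.simulate_annotations(small_config, truth)
    return matrix, truth, annotations


@pytest.fixture(scope="session")
def planted_experiment():
    """Simulation sized for reliable planted-signal recovery (larger DE
    set and stronger enrichment odds than the pipeline default)."""
    config = dq.SimulationConfig(n_genes=800, seed=9, enrichment_odds=8.0)
    matrix, truth = dq.simulate_counts(config)
    annotations = dq.simulate_annotations(config, truth)
    return matrix, truth, annotations


@pytest.fixture
def toy_matrix():
    """3 genes x 4 lanes, two tissue/treatment groups of 2 replicates."""
    counts = pd.DataFrame(
        {
            "l1": [10, 0, 5],
            "l2": [12, 0, 7],
            "l3": [30, 0, 5],
            "l4": [28, 0, 6],
        },
        index=["gA", "gB", "gC"],
    )
    samples = pd.DataFrame(
        {
            "lane": ["l1", "l2", "l3", "l4"],
            "tissue": ["shoot"] * 4,
            "treatment": ["NaOH", "NaOH", "ABA", "ABA"],
            "replicate": [1, 2, 1, 2],
        }
    ).set_index("lane", drop=False)
    return CountMatrix(counts=counts, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
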