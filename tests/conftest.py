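import numpy as np
import pytest

from cnaclone.model import default_prior
from cnaclone.simulator import (
    CloneTree,
    SimulationTruth,
    simulate_counts,
)


@pytest.fixture(scope="session")
def two_clone_sim():
    """Two clones, 200 cells per modality, one strong 1-vs-3 copy segment."""
    truth = SimulationTruth(
        tree=CloneTree([-1, 0], [{}, {1: 1, 3: 3}]),
        cn_matrix=np.array(
            [[2, 3, 2, 2, 2, 2], [2, 1, 2, 3, 2, 2]]
        ),
        proportions=np.array([0.5, 0.5]),
    )
    theta = {"RNA": np.full(6, 60.0), "ATAC": np.full(6, 40.0)}
    over = {"RNA": np.full(6, 50.0), "ATAC": np.full(6, 150.0)}
    return simulate_counts(
        truth, 200, theta, over, library_sd=0.2, seed=1234
    )


@pytest.fixture(scope="session")
def two_clone_prior(two_clone_sim):
    return default_prior(np.full(6, 2), H=4)


@pytest.fixture(scope="session")
def paired_sim():
    """Multiome-style dataset: shared barcodes and labels across assays."""
    truth = SimulationTruth(
        tree=CloneTree([-1, 0], [{}, {0: 4, 2: 1}]),
        cn_matrix=np.array([[2, 2, 2, 2, 2], [4, 2, 1, 2, 2]]),
        proportions=np.array([0.6, 0.4]),
    )
    theta = {"RNA": np.full(5, 60.0), "ATAC": np.full(5, 40.0)}
    over = {"RNA": np.full(5, 50.0), "ATAC": np.full(5, 150.0)}
    return simulate_counts(
        truth, 150, theta, over, library_sd=0.2, paired=True, seed=4321
    )
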