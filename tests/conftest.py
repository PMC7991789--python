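import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import fconn


@pytest.fixture(scope="session")
def small_spec() -> fconn.CohortSpec:
    """A 41-node, 5-per-group cohort used by fast integration tests."""
    return fconn.CohortSpec(
        group_sizes={"HC": 5, "FCNAD": 5, "FCAD": 5},
        n_nodes=41,
        module_sizes=(8, 8, 8, 5, 5, 3, 4),
        n_frames=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return fconn.generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_graph(n: int, density: float, seed: int) -> fconn.BinaryGraph:
    """Random simple graph fixture (not Erdos-Renyi exact, density-targeted)."""
    g_rng = np.random.default_rng(seed)
    adj = (g_rng.random((n, n)) < density).astype(np.uint8)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return fconn.BinaryGraph(adjacency=adj, sparsity=float(adj.sum() / (n * (n - 1))))
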