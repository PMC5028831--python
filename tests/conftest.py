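import numpy as np
import pytest

from txpipe.quantify import CountMatrix
from txpipe.synthetic import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=400, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_counts(small_cfg)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 4 samples, two groups, handmade."""
    counts = np.array([
        [10, 12, 100, 110],
        [0, 0, 0, 0],
        [50, 55, 5, 6],
        [200, 210, 220, 230],
    ])
    return CountMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        lengths=np.array([1000.0, 2000.0, 1500.0, 500.0]),
        counts=counts,
        sample_ids=["a1", "a2", "b1", "b2"],
        groups={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )
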