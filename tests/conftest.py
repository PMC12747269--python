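import numpy as np
import pytest
import scipy.sparse as sp

from wdge import CountMatrix, SynthConfig, generate_synthetic

BASE_SEED = 1  # seed of the shared synthetic base data used across tests


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """4 genes x 3 cells, handcrafted."""
    counts = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [5, 0, 3],
            [2, 2, 2],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array(["g1", "g2", "g3", "g4"]),
        np.array(["c1", "c2", "c3"]),
    )


@pytest.fixture(scope="session")
def small_synth() -> CountMatrix:
    """Small synthetic matrix for generic pipeline tests."""
    cm, _ = generate_synthetic(
        SynthConfig(n_cells=120, n_genes=400, seed=BASE_SEED)
    )
    return cm


@pytest.fixture(scope="session")
def base_cm() -> CountMatrix:
    """Full-scale synthetic base matrix: ~1,000 cells with ~100-fold depth
    variation and ~12,000 genes above the 30-count filter."""
    cm, _ = generate_synthetic(SynthConfig(seed=BASE_SEED))
    return cm
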