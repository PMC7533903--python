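import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from tcrqc import CountMatrix, SimConfig, simulate_droplets

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


def build_matrix(symbols, barcodes, dense):
    """CountMatrix from a dense (features x barcodes) array; ids mirror symbols."""
    return CountMatrix(
        feature_ids=[f"ID-{s}" for s in symbols],
        feature_symbols=list(symbols),
        barcodes=list(barcodes),
        counts=sp.csc_matrix(np.asarray(dense, dtype=np.int64)),
    )


@pytest.fixture
def toy_matrix():
    # 3 genes x 2 barcodes; entries (1,1)=5 and (3,2)=2 in 1-based MTX terms
    return build_matrix(
        ["GENEA", "GENEB", "MT-CO1"],
        ["AAAC-1", "CCCG-1"],
        [[5, 0], [0, 0], [0, 2]],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation shared across tests (seed fixed)."""
    config = SimConfig(seed=7)
    matrix, contigs, truth = simulate_droplets(config)
    return config, matrix, contigs, truth
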