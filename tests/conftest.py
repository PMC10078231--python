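import numpy as np
import pytest

import cooxnet as cx


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic metacommunity, shared across tests."""
    return cx.simulate(cx.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_classifications(default_sim):
    """Significant pairs of the default community, classified."""
    matrix, meta, truth = default_sim
    filtered = cx.filter_taxa(matrix)
    tests = cx.all_pairs(filtered, significant_only=True)
    return cx.classify_pairs(tests, meta, filtered), filtered, meta, truth


@pytest.fixture
def tiny_matrix():
    """4 taxa x 6 samples with hand-set abundances."""
    rel = np.array([
        [0.5, 0.5, 0.5, 0.0, 0.0, 0.0],
        [0.5, 0.5, 0.5, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.5, 0.5, 0.5],
        [0.0, 0.0, 0.0, 0.5, 0.5, 0.5],
    ])
    return cx.CommunityMatrix(
        taxa=["tA", "tB", "tC", "tD"],
        samples=[f"s{i}" for i in range(6)],
        rel_abundance=rel)
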