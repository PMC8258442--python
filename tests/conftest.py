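import numpy as np
import pytest

from thicknet import NodeSet, WeightedNetwork


@pytest.fixture
def toy_weighted():
    """4-node weighted network with hand-checkable thresholding/measures."""
    labels = ("lh_a", "lh_b", "lh_c", "lh_d")
    M = np.zeros((4, 4))
    pairs = {
        (0, 1): 0.9, (0, 2): 0.5, (0, 3): 0.2,
        (1, 2): 0.7, (1, 3): 0.1, (2, 3): 0.4,
    }
    for (i, j), v in pairs.items():
        M[i, j] = M[j, i] = v
    return WeightedNetwork(labels, M)


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles (6 nodes)."""
    W = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[i, j] = W[j, i] = 1.0
    return W


@pytest.fixture
def nodes12():
    return NodeSet.from_columns("twelve", [f"lh_r{i:02d}" for i in range(12)])


@pytest.fixture
def nodes6():
    return NodeSet.from_columns("six", [f"lh_r{i}" for i in range(6)])
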