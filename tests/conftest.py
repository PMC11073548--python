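import numpy as np
import pytest

from topofilt import WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def four_node_net():
    """Complete 4-node network with distinct weights (filtration walk-through)."""
    w = np.array(
        [
            [0.0, 0.5, 0.8, 0.2],
            [0.5, 0.0, 0.6, 0.9],
            [0.8, 0.6, 0.0, 0.3],
            [0.2, 0.9, 0.3, 0.0],
        ]
    )
    return WeightedNetwork(w)


def random_symmetric_distance_matrix(rng, n, scale=1.0):
    """Symmetric nonnegative matrix with zero diagonal (a plausible distance matrix)."""
    a = rng.uniform(0.1, 1.0, size=(n, n)) * scale
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
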