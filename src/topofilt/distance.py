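"""Wasserstein-type topological distances between networks.

For graph filtrations the 0D/1D persistence diagrams are one-dimensional
sorted value sets (births/deaths), so the 2-Wasserstein distance reduces to
order statistics: match the i-th smallest value of one network with the i-th
smallest of the other and sum squared differences,

    d0(G1, G2) = sum_i (b_i^1 - b_i^2)^2,
    d1(G1, G2) = sum_i (d_i^1 - d_i^2)^2.

These are the squared forms as used throughout the inference; they are not
square-rooted by default (``root=True`` gives the metric variant).  The
combined distance is ``d = w0*d0 + w1*d1`` with equal weights by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import IncompatibleNetworksError, InvalidParameterError
from .network import BirthDeathDecomposition, WeightedNetwork, birth_death_decompose

__all__ = [
    "GroupedDistanceMatrix",
    "wasserstein0",
    "wasserstein1",
    "combined_distance",
    "pairwise_distances",
    "matrix_euclidean_distance",
    "pairwise_matrix_euclidean",
]


@dataclass(frozen=True)
class GroupedDistanceMatrix:
    """Pairwise distance matrices for two stacked groups of networks.

    The first ``m`` rows/columns are group 1, the next ``n`` group 2.
    ``D01 = w0*D0 + w1*D1`` elementwise with the configured weights.
    """

    D0: np.ndarray
    D1: np.ndarray
    D01: np.ndarray
    labels: np.ndarray  # 0 for group 1, 1 for group 2
    w0: float = 1.0
    w1: float = 1.0

    @property
    def m(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n(self) -> int:
        return int(np.sum(self.labels == 1))


def _check_weights_nonneg(w0: float, w1: float) -> None:
    if w0 < 0 or w1 < 0:
        raise InvalidParameterError(f"distance weights must be nonnegative, got {w0}, {w1}")


def _sq_diff_sum(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    if len(a) != len(b):
        raise IncompatibleNetworksError(
            f"{kind} sets have different sizes ({len(a)} vs {len(b)}); "
            "networks must have matching diagram sizes"
        )
    if len(a) == 0:
        return 0.0
    return float(np.sum((a - b) ** 2))


def wasserstein0(
    netA: WeightedNetwork | BirthDeathDecomposition,
    netB: WeightedNetwork | BirthDeathDecomposition,
    root: bool = False,
) -> float:
    """0D (connected-component) distance from order-matched sorted births."""
    da = netA if isinstance(netA, BirthDeathDecomposition) else birth_death_decompose(netA)
    db = netB if isinstance(netB, BirthDeathDecomposition) else birth_death_decompose(netB)
    d = _sq_diff_sum(da.births, db.births, "birth")
    return float(np.sqrt(d)) if root else d


def wasserstein1(
    netA: WeightedNetwork | BirthDeathDecomposition,
    netB: WeightedNetwork | BirthDeathDecomposition,
    root: bool = False,
) -> float:
    """1D (cycle) distance from order-matched sorted deaths.

    Two trees both have empty death sets; their distance is 0 by convention.
    """
    da = netA if isinstance(netA, BirthDeathDecomposition) else birth_death_decompose(netA)
    db = netB if isinstance(netB, BirthDeathDecomposition) else birth_death_decompose(netB)
    d = _sq_diff_sum(da.deaths, db.deaths, "death")
    return float(np.sqrt(d)) if root else d


def combined_distance(
    netA: WeightedNetwork | BirthDeathDecomposition,
    netB: WeightedNetwork | BirthDeathDecomposition,
    w0: float = 1.0,
    w1: float = 1.0,
) -> float:
    """Weighted combination ``w0*d0 + w1*d1`` (equal weights by default)."""
    _check_weights_nonneg(w0, w1)
    return w0 * wasserstein0(netA, netB) + w1 * wasserstein1(netA, netB)


def _stack_diagrams(nets, kind: str):
    """Stack equal-length sorted birth (kind='births') or death arrays row-wise."""
    arrays = [getattr(bd, kind) for bd in nets]
    sizes = {len(a) for a in arrays}
    if len(sizes) > 1:
        raise IncompatibleNetworksError(
            f"{kind} sets have heterogeneous sizes {sorted(sizes)}"
        )
    size = sizes.pop()
    if size == 0:
        return np.zeros((len(arrays), 0))
    return np.vstack(arrays)


def pairwise_distances(
    group1,
    group2,
    w0: float = 1.0,
    w1: float = 1.0,
) -> GroupedDistanceMatrix:
    """All-pairs topological distances for two groups of networks.

    Decompositions are computed once per network; the pairwise sums of
    squared differences are then evaluated on the stacked sorted birth and
    death arrays.
    """
    _check_weights_nonneg(w0, w1)
    if len(group1) < 1 or len(group2) < 1:
        raise InvalidParameterError("both groups need at least one network")
    nets = list(group1) + list(group2)
    qs = {net.q for net in nets}
    if len(qs) > 1:
        raise IncompatibleNetworksError(f"heterogeneous node counts {sorted(qs)}")
    decomps = [birth_death_decompose(net) for net in nets]
    B = _stack_diagrams(decomps, "births")
    D = _stack_diagrams(decomps, "deaths")
    D0 = cdist(B, B, "sqeuclidean") if B.shape[1] else np.zeros((len(nets), len(nets)))
    D1 = cdist(D, D, "sqeuclidean") if D.shape[1] else np.zeros((len(nets), len(nets)))
    # enforce exact symmetry (cdist is symmetric up to fp association order)
    D0 = (D0 + D0.T) / 2.0
    D1 = (D1 + D1.T) / 2.0
    np.fill_diagonal(D0, 0.0)
    np.fill_diagonal(D1, 0.0)
    labels = np.array([0] * len(group1) + [1] * len(group2))
    return GroupedDistanceMatrix(D0=D0, D1=D1, D01=w0 * D0 + w1 * D1, labels=labels, w0=w0, w1=w1)


def matrix_euclidean_distance(netA: WeightedNetwork, netB: WeightedNetwork) -> float:
    """Baseline L2 norm between weight matrices over the upper triangle.

    Unlike the topological distances this is sensitive to node labelling.
    """
    if netA.q != netB.q:
        raise IncompatibleNetworksError(f"node counts differ ({netA.q} vs {netB.q})")
    iu = np.triu_indices(netA.q, k=1)
    diff = netA.weights[iu] - netB.weights[iu]
    return float(np.sqrt(np.sum(diff**2)))


def pairwise_matrix_euclidean(group1, group2) -> np.ndarray:
    """All-pairs matrix-Euclidean (L2) distances for two stacked groups."""
    nets = list(group1) + list(group2)
    qs = {net.q for net in nets}
    if len(qs) > 1:
        raise IncompatibleNetworksError(f"heterogeneous node counts {sorted(qs)}")
    q = qs.pop()
    iu = np.triu_indices(q, k=1)
    X = np.vstack([net.weights[iu] for net in nets])
    D = cdist(X, X, "euclidean")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D
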