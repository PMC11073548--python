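"""Seeded generators for every synthetic input class used in tests and demos.

Four families:

* **Point-cloud networks** — nodes on a planar circular pattern (default two
  tangent unit circles) with isotropic Gaussian coordinate noise
  N(0, 0.3^2); connectivity is the pairwise Euclidean distance.  Groups that
  differ only by a rotation of the pattern are topologically equivalent, the
  benchmark for label-free topological distances.
* **Matched-weight trees** — two trees with different shapes but identical
  sorted edge weights: their 0D/1D diagrams coincide, so every topological
  distance vanishes while the matrix-Euclidean distance does not.
* **Factor-model feature tables** — subject-by-node tables with a single
  shared factor, giving a dial (rho) for the inter-node correlation of the
  resulting structural covariance networks.
* **Random complete networks** — i.i.d. distinct edge weights, the fodder
  for decomposition oracles and exchangeable nulls.

All generators take a ``seed`` (int or ``numpy.random.Generator``) and are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .covariance import FeatureTable
from .exceptions import InvalidParameterError
from .network import WeightedNetwork

__all__ = [
    "PointCloudSpec",
    "circle_pattern_networks",
    "matched_weight_trees",
    "factor_model_table",
    "random_complete_network",
]


@dataclass(frozen=True)
class PointCloudSpec:
    """Parameters of a planar circular point-cloud pattern.

    ``pattern`` is one of ``"two_circles"`` (two tangent unit circles, a
    figure-eight; rotations are geometrically meaningful) or ``"circle"``
    (a single unit circle centred at the origin).
    """

    n_nodes: int = 60
    noise_sd: float = 0.3
    rotation: float = 0.0
    pattern: str = "two_circles"

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise InvalidParameterError("n_nodes must be >= 3")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if self.pattern not in ("two_circles", "circle"):
            raise InvalidParameterError(f"unknown pattern {self.pattern!r}")


def _pattern_points(spec: PointCloudSpec) -> np.ndarray:
    """Noise-free node coordinates for the rotated pattern.

    Node phases sit on a fixed, evenly spaced grid in the laboratory frame;
    the rotation is applied to the pattern (for ``two_circles``, to the
    circle centres).  Anchoring the phase grid to the lab frame keeps node
    indexing comparable across rotations, which is what lets a
    label-sensitive baseline (matrix L2) tell rotated groups apart even
    though the point clouds are topologically identical.  A rigid rotation
    of the sampled points themselves would leave all pairwise distances
    unchanged and make rotation a no-op.
    """
    # exact periodicity: 2*pi reduces to 0.0
    theta = math.remainder(spec.rotation, 2.0 * math.pi)
    if spec.pattern == "circle":
        phases = 2.0 * np.pi * np.arange(spec.n_nodes) / spec.n_nodes
        return np.column_stack([np.cos(phases), np.sin(phases)])
    # two tangent unit circles with centres at R(theta) * (+-1, 0)
    n1 = spec.n_nodes // 2
    n2 = spec.n_nodes - n1
    c = np.array([math.cos(theta), math.sin(theta)])
    # canonical block order: nodes 1..n/2 sit on the circle whose centre is
    # lexicographically larger in the lab frame (x, then y).  A rotation by
    # pi is then an exact symmetry of the generated configuration, so the
    # two "horizontal" rotations (0, pi) share one base geometry and the two
    # "vertical" ones (pi/2, 3pi/2) another.
    c[np.abs(c) < 1e-12] = 0.0  # snap axis-aligned rotations exactly
    if c[0] < 0 or (c[0] == 0 and c[1] < 0):
        c = -c
    centers = np.vstack([c, -c])
    p1 = 2.0 * np.pi * np.arange(n1) / n1
    p2 = 2.0 * np.pi * np.arange(n2) / n2
    pts1 = centers[0] + np.column_stack([np.cos(p1), np.sin(p1)])
    pts2 = centers[1] + np.column_stack([np.cos(p2), np.sin(p2)])
    return np.vstack([pts1, pts2])


def circle_pattern_networks(
    spec: PointCloudSpec,
    n_networks: int = 5,
    seed=None,
    affinity: bool = True,
) -> list[WeightedNetwork]:
    """Sample noisy point-cloud networks from a circular pattern.

    Each network adds fresh N(0, noise_sd^2) noise to both coordinates of
    every node and takes pairwise Euclidean distances as connectivity.  With
    ``affinity=True`` (default) the weights are ``max(dist) - dist`` so that
    strongly connected (close) node pairs carry large weights, matching the
    filtration convention that removes weak edges first; raw distances have
    the opposite polarity.
    """
    rng = np.random.default_rng(seed)
    base = _pattern_points(spec)
    nets = []
    for _ in range(n_networks):
        pts = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        d = pdist(pts)
        if affinity:
            d = d.max() - d
        w = squareform(d)
        # complete-graph semantics even if one transformed weight is exactly 0
        nets.append(WeightedNetwork(w, mask=np.ones_like(w, dtype=bool)))
    return nets


_TREE_BUILDERS = {
    "path": lambda q, rng: [(i, i + 1) for i in range(q - 1)],
    "star": lambda q, rng: [(0, i) for i in range(1, q)],
    "random": lambda q, rng: list(
        nx.random_labeled_tree(q, seed=np.random.RandomState(rng.integers(2**31))).edges()
    ),
}


def matched_weight_trees(
    q: int,
    topology_a: str = "path",
    topology_b: str = "star",
    seed=None,
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Two trees with the given shapes carrying identical sorted edge weights.

    Both trees receive the same multiset of ``q - 1`` distinct positive
    weights ``w1 < ... < w_{q-1}``, so their birth sets coincide and both
    death sets are empty: all topological distances between them vanish.
    """
    if q < 3:
        raise InvalidParameterError("trees need q >= 3")
    for shape in (topology_a, topology_b):
        if shape not in _TREE_BUILDERS:
            raise InvalidParameterError(
                f"unknown tree shape {shape!r}; choose from {sorted(_TREE_BUILDERS)}"
            )
    rng = np.random.default_rng(seed)
    weights = np.sort(rng.uniform(0.1, 1.0, size=q - 1))
    while len(np.unique(weights)) < q - 1:  # pragma: no cover - a.s. never
        weights = np.sort(rng.uniform(0.1, 1.0, size=q - 1))

    def build(shape: str) -> WeightedNetwork:
        w = np.zeros((q, q))
        for (i, j), wt in zip(_TREE_BUILDERS[shape](q, rng), weights):
            w[i, j] = w[j, i] = wt
        return WeightedNetwork(w)

    return build(topology_a), build(topology_b)


def factor_model_table(
    n_subjects: int,
    q: int,
    rho: float,
    seed=None,
    subject_prefix: str = "s",
) -> FeatureTable:
    """Subject-by-node table from a one-factor model with target correlation rho.

    ``x[s, k] = sqrt(rho) * f[s] + sqrt(1 - rho) * e[s, k]`` with standard
    normal factor and noise, so every off-diagonal node pair has expected
    correlation rho.
    """
    if not 0.0 <= rho < 1.0:
        raise InvalidParameterError(f"rho must be in [0, 1), got {rho}")
    if n_subjects < 2 or q < 2:
        raise InvalidParameterError("need n_subjects >= 2 and q >= 2")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_subjects)
    e = rng.standard_normal((n_subjects, q))
    values = np.sqrt(rho) * f[:, None] + np.sqrt(1.0 - rho) * e
    subjects = tuple(f"{subject_prefix}{i + 1:03d}" for i in range(n_subjects))
    nodes = tuple(f"node{k + 1:03d}" for k in range(q))
    return FeatureTable(subjects, nodes, values)


def random_complete_network(
    q: int,
    weight_distribution: str = "uniform",
    seed=None,
) -> WeightedNetwork:
    """Complete network with i.i.d. distinct edge weights (ties redrawn).

    ``weight_distribution``: ``"uniform"`` on (0, 1) or ``"exponential"``
    with unit rate.  Both are strictly positive, so the zero-means-missing
    default convention leaves the graph complete.
    """
    if q < 2:
        raise InvalidParameterError("need q >= 2")
    rng = np.random.default_rng(seed)
    r = q * (q - 1) // 2
    samplers = {
        "uniform": lambda size: rng.uniform(size=size),
        "exponential": lambda size: rng.exponential(size=size),
    }
    if weight_distribution not in samplers:
        raise InvalidParameterError(f"unknown weight distribution {weight_distribution!r}")
    draw = samplers[weight_distribution]
    ww = draw(r)
    while len(np.unique(ww)) < r or np.any(ww == 0):  # pragma: no cover - a.s. never
        ww = draw(r)
    return WeightedNetwork(squareform(ww))
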