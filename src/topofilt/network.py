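"""Weighted networks, graph filtration, birth-death decomposition, Betti curves.

A brain (or any) network is modelled as a weighted graph ``G = (V, w)`` on
``q`` nodes with a symmetric weight matrix ``w``.  The *graph filtration* is
the nested family of binary graphs ``G_eps`` keeping the edges with
``w_ij > eps``; as ``eps`` sweeps upward, edges disappear one at a time,
connected components are born (beta0 grows) and cycles die (beta1 shrinks).

Every edge weight belongs to exactly one of two sets:

* the **birth set** — weights of a maximum spanning forest (MSF); each such
  edge, when removed, creates a new connected component;
* the **death set** — all non-MSF weights; each such edge closes a cycle and
  its removal destroys that cycle.

The birth set is the 0D persistence diagram and the death set the 1D
persistence diagram of the filtration.  For a connected complete graph the
sets have sizes ``q - 1`` and ``(q - 1)(q - 2)/2``.  Both Betti curves then
follow from the sorted sets alone, using the Euler characteristic
``beta0 - beta1 = q - E(eps)``; no per-threshold component counting is
needed, which is what keeps the whole construction at O(q^2 log q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from networkx.utils import UnionFind

from .exceptions import InvalidParameterError

__all__ = [
    "WeightedNetwork",
    "EdgeRecord",
    "BirthDeathDecomposition",
    "BettiCurve",
    "threshold_graph",
    "birth_death_decompose",
    "betti_curves",
    "default_threshold_grid",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeRecord:
    """A single undirected edge ``(i, j)`` with ``i < j`` and its weight."""

    i: int
    j: int
    weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise InvalidParameterError(
                f"edge indices must satisfy 0 <= i < j, got ({self.i}, {self.j})"
            )


class WeightedNetwork:
    """Symmetric weighted graph on ``q`` nodes with zero diagonal.

    Parameters
    ----------
    weights
        Square symmetric real matrix; the diagonal must be zero and every
        entry finite.  Symmetry is required exactly on ingest; pass
        ``symmetrize=True`` to average ``(w + w.T)/2`` with a warning.
    node_labels
        Optional sequence of ``q`` node identifiers.
    mask
        Optional boolean matrix marking which off-diagonal entries are edges.
        By default the edges are the nonzero entries, the natural convention
        for sparse count data (tract count 0 = no connection).  Pass an
        all-True mask to force complete-graph semantics when genuine zero
        weights occur (e.g. affinity-transformed distances).
    """

    __slots__ = ("weights", "node_labels", "mask")

    def __init__(
        self,
        weights,
        node_labels: Sequence | None = None,
        mask=None,
        symmetrize: bool = False,
    ) -> None:
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise InvalidParameterError("network needs at least one node")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite")
        if not np.array_equal(w, w.T):
            if symmetrize:
                warnings.warn("asymmetric weights symmetrized as (w + w.T)/2")
                w = (w + w.T) / 2.0
            else:
                raise InvalidParameterError(
                    "weights must be exactly symmetric (use symmetrize=True to average)"
                )
        if np.any(np.diag(w) != 0):
            raise InvalidParameterError("diagonal must be zero (no self-loops)")
        if node_labels is not None and len(node_labels) != w.shape[0]:
            raise InvalidParameterError("node_labels length must equal node count")
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != w.shape:
                raise InvalidParameterError("mask shape must match weights")
            if not np.array_equal(mask, mask.T):
                raise InvalidParameterError("mask must be symmetric")
            mask = mask.copy()
            np.fill_diagonal(mask, False)
        self.weights = w
        self.node_labels = tuple(node_labels) if node_labels is not None else None
        self.mask = mask

    @property
    def q(self) -> int:
        """Number of nodes."""
        return self.weights.shape[0]

    def edge_mask(self):
        """Boolean matrix of existing edges (off-diagonal)."""
        if self.mask is not None:
            return self.mask
        m = self.weights != 0
        np.fill_diagonal(m, False)
        return m

    def edges(self) -> list[EdgeRecord]:
        """All existing edges as records with ``i < j``."""
        m = np.triu(self.edge_mask(), k=1)
        ii, jj = np.nonzero(m)
        return [EdgeRecord(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def edge_weights(self):
        """1D array of existing edge weights (upper triangle, unsorted)."""
        m = np.triu(self.edge_mask(), k=1)
        return self.weights[m]

    def is_complete(self) -> bool:
        m = self.edge_mask()
        return bool(np.all(m[~np.eye(self.q, dtype=bool)]))

    def relabel(self, perm) -> "WeightedNetwork":
        """Return the network with nodes permuted by ``perm`` (new[i] = old[perm[i]])."""
        perm = np.asarray(perm)
        w = self.weights[np.ix_(perm, perm)]
        mask = None if self.mask is None else self.mask[np.ix_(perm, perm)]
        labels = None
        if self.node_labels is not None:
            labels = [self.node_labels[p] for p in perm]
        return WeightedNetwork(w, node_labels=labels, mask=mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"WeightedNetwork(q={self.q}, edges={int(self.edge_mask().sum() // 2)})"


@dataclass(frozen=True)
class BirthDeathDecomposition:
    """Sorted birth/death value sets with their edges.

    ``births`` are the weights of a maximum spanning forest (ascending);
    ``deaths`` are all remaining edge weights (ascending).  ``c`` is the
    number of connected components of the fully weighted graph, so
    ``len(births) == q - c``.
    """

    births: np.ndarray
    deaths: np.ndarray
    birth_edges: tuple[EdgeRecord, ...]
    death_edges: tuple[EdgeRecord, ...]
    q: int
    c: int

    @property
    def n_births(self) -> int:
        return len(self.births)

    @property
    def n_deaths(self) -> int:
        return len(self.deaths)


@dataclass(frozen=True)
class BettiCurve:
    """beta0 and beta1 evaluated on an ascending grid of filtration values."""

    thresholds: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.beta0) == len(self.beta1)):
            raise InvalidParameterError("thresholds/beta0/beta1 lengths differ")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def threshold_graph(net: WeightedNetwork, eps: float):
    """Binary adjacency of the filtration graph ``G_eps``.

    Entry ``(i, j)`` is 1 iff ``w_ij > eps`` (strict) and ``i != j``.  The
    strict inequality matters exactly at event points: the edge whose weight
    equals ``eps`` is already gone at its own threshold.
    """
    if not np.isfinite(eps):
        raise InvalidParameterError(f"threshold must be finite, got {eps}")
    adj = (net.weights > eps) & net.edge_mask()
    return adj.astype(np.int8)


def _sorted_edge_arrays(net: WeightedNetwork):
    """Edges sorted by (weight desc, i asc, j asc) — the deterministic greedy order."""
    m = np.triu(net.edge_mask(), k=1)
    ii, jj = np.nonzero(m)
    ww = net.weights[ii, jj]
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, -ww))
    return ii[order], jj[order], ww[order]


def birth_death_decompose(net: WeightedNetwork) -> BirthDeathDecomposition:
    """Partition the edge-weight multiset into births (MSF) and deaths (rest).

    Kruskal's greedy algorithm on edges sorted by decreasing weight with
    union-find: an edge joining two distinct components is a birth edge
    (it belongs to the maximum spanning forest), otherwise it closes a cycle
    and is a death edge.  Ties are broken by ascending ``(i, j)`` so the run
    is deterministic; the weight multiset partition does not depend on the
    tie-break.  O(q^2 log q) in the edge sort.
    """
    ii, jj, ww = _sorted_edge_arrays(net)
    uf = UnionFind(range(net.q))
    birth_edges: list[EdgeRecord] = []
    death_edges: list[EdgeRecord] = []
    for i, j, w in zip(ii, jj, ww):
        if uf[i] != uf[j]:
            uf.union(i, j)
            birth_edges.append(EdgeRecord(int(i), int(j), float(w)))
        else:
            death_edges.append(EdgeRecord(int(i), int(j), float(w)))
    # greedy visits weights in descending order; reverse for ascending sets
    birth_edges.reverse()
    death_edges.reverse()
    births = np.array([e.weight for e in birth_edges], dtype=float)
    deaths = np.sort(np.array([e.weight for e in death_edges], dtype=float))
    death_edges.sort(key=lambda e: e.weight)
    return BirthDeathDecomposition(
        births=births,
        deaths=deaths,
        birth_edges=tuple(birth_edges),
        death_edges=tuple(death_edges),
        q=net.q,
        c=net.q - len(birth_edges),
    )


def betti_curves(
    net: WeightedNetwork,
    thresholds,
    decomposition: BirthDeathDecomposition | None = None,
) -> BettiCurve:
    """Betti-0 and Betti-1 curves over ``thresholds`` from one decomposition pass.

    ``beta0(eps) = q - #{births > eps}`` (each surviving MSF edge merges two
    components) and ``beta1(eps) = #{deaths > eps}`` (each surviving non-MSF
    edge carries one independent cycle).  Equivalently
    ``beta1 = E(eps) - q + beta0`` by the Euler characteristic.
    """
    eps = np.asarray(thresholds, dtype=float)
    if eps.size == 0:
        raise InvalidParameterError("threshold sequence must be non-empty")
    if not np.all(np.isfinite(eps)):
        raise InvalidParameterError("thresholds must be finite")
    if np.any(np.diff(eps) < 0):
        warnings.warn("thresholds not ascending; sorting")
        eps = np.sort(eps)
    bd = decomposition or birth_death_decompose(net)
    # #{x > eps} on a sorted array via searchsorted
    beta0 = net.q - (len(bd.births) - np.searchsorted(bd.births, eps, side="right"))
    beta1 = len(bd.deaths) - np.searchsorted(bd.deaths, eps, side="right")
    return BettiCurve(thresholds=eps, beta0=beta0.astype(int), beta1=beta1.astype(int))


def default_threshold_grid(
    net: WeightedNetwork, n_points: int = 100, mode: str = "linear"
):
    """Filtration-value grid for Betti curves.

    ``mode="linear"``: ``n_points`` evenly spaced values from just below the
    minimum edge weight (so the first point shows the full graph) to the
    maximum.  ``mode="exact"``: all distinct edge weights — the complete set
    of filtration events.
    """
    ew = net.edge_weights()
    if ew.size == 0:
        raise InvalidParameterError("network has no edges")
    lo, hi = float(ew.min()), float(ew.max())
    if mode == "exact":
        return np.unique(ew)
    if mode != "linear":
        raise InvalidParameterError(f"unknown grid mode {mode!r}")
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    if lo == hi:
        warnings.warn("all edge weights equal; degenerate grid")
        span = abs(lo) if lo != 0 else 1.0
        return np.linspace(lo - 1e-3 * span, hi, n_points)
    delta = 1e-9 * (hi - lo)
    return np.linspace(lo - delta, hi, n_points)
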