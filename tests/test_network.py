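"""Graph filtration, birth-death decomposition, and Betti curves."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from topofilt import (
    InvalidParameterError,
    WeightedNetwork,
    betti_curves,
    birth_death_decompose,
    default_threshold_grid,
    random_complete_network,
    threshold_graph,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exhaustive_max_spanning_tree(net):
    """Best spanning tree by enumerating all edge subsets of size q-1 (tiny q only)."""
    edges = net.edges()
    best, best_w = None, -np.inf
    for combo in itertools.combinations(edges, net.q - 1):
        g = nx.Graph()
        g.add_nodes_from(range(net.q))
        g.add_edges_from((e.i, e.j) for e in combo)
        if nx.is_connected(g):
            total = sum(e.weight for e in combo)
            if total > best_w:
                best_w, best = total, combo
    return {(e.i, e.j) for e in best}, best_w


def component_count(adjacency):
    n_comp, _ = connected_components(adjacency, directed=False)
    return n_comp


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

class TestWeightedNetworkValidation:
    def test_rejects_asymmetry_unless_symmetrize(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidParameterError):
            WeightedNetwork(w)
        with pytest.warns(UserWarning):
            net = WeightedNetwork(w, symmetrize=True)
        assert net.weights[0, 1] == 1.5

    @pytest.mark.parametrize(
        "w",
        [
            np.array([[1.0, 0.5], [0.5, 0.0]]),  # nonzero diagonal
            np.array([[0.0, np.nan], [np.nan, 0.0]]),  # non-finite
            np.zeros((2, 3)),  # non-square
        ],
    )
    def test_rejects_invalid_matrices(self, w):
        with pytest.raises(InvalidParameterError):
            WeightedNetwork(w)

    def test_zero_weights_are_missing_edges_by_default(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        net = WeightedNetwork(w)
        assert len(net.edges()) == 1
        complete = WeightedNetwork(w, mask=np.ones((3, 3), dtype=bool))
        assert len(complete.edges()) == 3


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestThresholdGraph:
    def test_strict_inequality_at_boundary(self):
        w = np.array([[0.0, 0.7], [0.7, 0.0]])
        net = WeightedNetwork(w)
        assert threshold_graph(net, 0.7).sum() == 0
        assert threshold_graph(net, 0.7 - 1e-12).sum() == 2

    def test_below_min_weight_gives_complete_adjacency(self, four_node_net):
        adj = threshold_graph(four_node_net, 0.0)
        assert adj.sum() == 4 * 3

    def test_nonfinite_threshold_rejected(self, four_node_net):
        with pytest.raises(InvalidParameterError):
            threshold_graph(four_node_net, np.nan)

    def test_one_edge_lost_per_event_with_distinct_weights(self, four_node_net):
        # direct enumeration: at each sorted weight exactly one edge disappears
        weights = np.sort(four_node_net.edge_weights())
        counts = [threshold_graph(four_node_net, eps).sum() // 2 for eps in weights]
        expected = list(range(len(weights) - 1, -1, -1))
        assert counts == expected


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

class TestBirthDeathDecomposition:
    def test_complete_graph_cardinalities(self, rng):
        q = 4
        bd = birth_death_decompose(random_complete_network(q, seed=rng))
        assert bd.n_births == q - 1
        assert bd.n_deaths == (q - 1) * (q - 2) // 2

    def test_single_edge(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.7
        bd = birth_death_decompose(WeightedNetwork(w))
        assert bd.births.tolist() == [0.7]
        assert bd.n_deaths == 0

    def test_partition_of_edge_weight_multiset(self, rng):
        for _ in range(20):
            q = int(rng.integers(3, 15))
            net = random_complete_network(q, seed=rng)
            bd = birth_death_decompose(net)
            recon = np.sort(np.concatenate([bd.births, bd.deaths]))
            assert np.array_equal(recon, np.sort(net.edge_weights()))

    def test_birth_edges_match_exhaustive_spanning_tree_enumeration(self, rng):
        for _ in range(25):
            q = int(rng.integers(3, 6))
            net = random_complete_network(q, seed=rng)
            bd = birth_death_decompose(net)
            oracle_edges, oracle_w = exhaustive_max_spanning_tree(net)
            assert {(e.i, e.j) for e in bd.birth_edges} == oracle_edges
            assert np.isclose(bd.births.sum(), oracle_w)

    def test_birth_weights_match_networkx_mst(self, rng):
        # independent implementation check at sizes beyond enumeration
        for _ in range(25):
            q = int(rng.integers(4, 9))
            net = random_complete_network(q, seed=rng)
            bd = birth_death_decompose(net)
            g = nx.from_numpy_array(net.weights)
            mst_w = sorted(d["weight"] for _, _, d in nx.maximum_spanning_edges(g))
            assert np.allclose(bd.births, mst_w)

    def test_disconnected_network_births_equal_q_minus_c(self):
        # two separate edges on 5 nodes: 2 components + 1 isolated node = 3
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.4
        w[2, 3] = w[3, 2] = 0.6
        bd = birth_death_decompose(WeightedNetwork(w))
        assert bd.c == 3
        assert bd.n_births == 5 - 3
        assert bd.n_deaths == 0

    def test_permutation_invariance_of_value_sets(self, rng):
        net = random_complete_network(9, seed=rng)
        perm = rng.permutation(net.q)
        bd1 = birth_death_decompose(net)
        bd2 = birth_death_decompose(net.relabel(perm))
        assert np.allclose(bd1.births, bd2.births)
        assert np.allclose(bd1.deaths, bd2.deaths)

    def test_tied_weights_still_partition_weights_deterministically(self):
        w = squareform(np.array([0.5, 0.5, 0.5, 0.2, 0.2, 0.9]))
        net = WeightedNetwork(w)
        bd1 = birth_death_decompose(net)
        bd2 = birth_death_decompose(net)
        assert np.array_equal(bd1.births, bd2.births)
        assert bd1.n_births == 3 and bd1.n_deaths == 3
        recon = np.sort(np.concatenate([bd1.births, bd1.deaths]))
        assert np.array_equal(recon, np.sort(net.edge_weights()))


# ---------------------------------------------------------------------------
# Betti curves
# ---------------------------------------------------------------------------

class TestBettiCurves:
    def test_full_and_empty_graph_limits(self, rng):
        q = 7
        net = random_complete_network(q, seed=rng)
        lo = net.edge_weights().min() - 0.1
        hi = net.edge_weights().max()
        curve = betti_curves(net, [lo, hi])
        assert (curve.beta0[0], curve.beta1[0]) == (1, (q - 1) * (q - 2) // 2)
        assert (curve.beta0[-1], curve.beta1[-1]) == (q, 0)

    def test_beta0_matches_component_counting_and_euler_identity(self, rng):
        for _ in range(30):
            q = int(rng.integers(3, 20))
            net = random_complete_network(q, seed=rng)
            eps = default_threshold_grid(net, mode="exact")
            curve = betti_curves(net, eps)
            for k, e in enumerate(eps):
                adj = threshold_graph(net, e)
                n_edges = adj.sum() // 2
                assert curve.beta0[k] == component_count(adj)
                assert curve.beta0[k] - curve.beta1[k] == q - n_edges

    def test_monotonicity(self, rng):
        net = random_complete_network(12, seed=rng)
        curve = betti_curves(net, default_threshold_grid(net, n_points=64))
        assert np.all(np.diff(curve.beta0) >= 0)
        assert np.all(np.diff(curve.beta1) <= 0)

    def test_unsorted_thresholds_sorted_with_warning(self, four_node_net):
        with pytest.warns(UserWarning):
            curve = betti_curves(four_node_net, [0.9, 0.1])
        assert curve.thresholds[0] < curve.thresholds[1]

    def test_empty_threshold_sequence_rejected(self, four_node_net):
        with pytest.raises(InvalidParameterError):
            betti_curves(four_node_net, [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_euler_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(3, 12))
        net = random_complete_network(q, seed=rng)
        eps = rng.uniform(-0.2, 1.2, size=10)
        curve = betti_curves(net, np.sort(eps))
        for k, e in enumerate(curve.thresholds):
            n_edges = threshold_graph(net, e).sum() // 2
            assert curve.beta0[k] - curve.beta1[k] == q - n_edges


class TestThresholdGrid:
    def test_linear_grid_spans_weight_range(self, four_node_net):
        grid = default_threshold_grid(four_node_net, n_points=5)
        assert len(grid) == 5
        assert grid[0] <= four_node_net.edge_weights().min()
        assert grid[-1] == four_node_net.edge_weights().max()
        assert np.all(np.diff(grid) > 0)

    def test_exact_mode_lists_all_event_values(self, four_node_net):
        grid = default_threshold_grid(four_node_net, mode="exact")
        assert len(grid) == 6  # r = (q^2 - q)/2 distinct weights

    def test_exact_and_dense_curves_agree_at_shared_points(self, rng):
        net = random_complete_network(8, seed=rng)
        exact = default_threshold_grid(net, mode="exact")
        dense = np.unique(np.concatenate([exact, np.linspace(exact[0], exact[-1], 57)]))
        ce = betti_curves(net, exact)
        cd = betti_curves(net, dense)
        pos = np.searchsorted(dense, exact)
        assert np.array_equal(ce.beta0, cd.beta0[pos])
        assert np.array_equal(ce.beta1, cd.beta1[pos])

    def test_degenerate_equal_weights_warns(self):
        w = squareform(np.full(3, 0.5))
        with pytest.warns(UserWarning):
            grid = default_threshold_grid(WeightedNetwork(w), n_points=4)
        assert np.all(np.isfinite(grid))
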