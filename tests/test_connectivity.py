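"""Disjoint paths and average connectivity: analytic cases, oracles, invariants."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from chromgat.breakpoints import N_CHROMOSOMES
from chromgat.connectivity import (
    N_PAIRS,
    average_connectivity,
    brute_force_disjoint_paths,
    max_edge_disjoint_paths,
    pairwise_connectivity,
)
from chromgat.graphs import RearrangementGraph


def _graph(edges):
    return RearrangementGraph("s", "x", [(u, v, "unknown") for u, v in edges])


def _random_instance(rng, max_nodes=5, max_edges=8):
    n = int(rng.integers(2, max_nodes + 1))
    m = int(rng.integers(0, max_edges + 1))
    edges = [
        (int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1)))
        for _ in range(m)
    ]
    u, v = map(int, rng.choice(np.arange(1, n + 1), size=2, replace=False))
    return edges, u, v


def test_parallel_edges_add_capacity():
    assert max_edge_disjoint_paths(_graph([(2, 3), (2, 3)]), 2, 3) == 2


def test_single_path_through_middle_node():
    assert max_edge_disjoint_paths(_graph([(1, 2), (2, 3)]), 1, 3) == 1


def test_triangle_two_paths():
    g = _graph([(1, 2), (2, 3), (1, 3)])
    assert brute_force_disjoint_paths(g, 1, 3) == 2
    assert max_edge_disjoint_paths(g, 1, 3) == 2


def test_self_loops_are_ignored():
    g = _graph([(1, 2), (1, 1), (2, 2)])
    assert max_edge_disjoint_paths(g, 1, 2) == 1


def test_same_endpoint_rejected():
    with pytest.raises(ValueError):
        max_edge_disjoint_paths(_graph([]), 3, 3)


def test_oracle_refuses_large_graphs():
    with pytest.raises(ValueError):
        brute_force_disjoint_paths(_graph([(1, 2)] * 11), 1, 2)


def test_brute_force_empty_graph():
    assert brute_force_disjoint_paths(_graph([]), 1, 2) == 0


def test_flow_agrees_with_networkx_max_flow():
    """Independent cross-check: unit-capacity max flow vs networkx."""
    rng = np.random.default_rng(7)
    for _ in range(150):
        edges, u, v = _random_instance(rng, max_nodes=7, max_edges=14)
        mult = Counter(frozenset((a, b)) for a, b in edges if a != b)
        G = nx.Graph()
        G.add_nodes_from(range(1, 8))
        for pair, c in mult.items():
            a, b = tuple(pair)
            G.add_edge(a, b, capacity=c)
        ref = int(nx.maximum_flow_value(G, u, v)) if G.number_of_edges() else 0
        assert max_edge_disjoint_paths(_graph(edges), u, v) == ref


def test_symmetry_and_degree_bound():
    rng = np.random.default_rng(11)
    for _ in range(100):
        edges, u, v = _random_instance(rng, max_nodes=6, max_edges=12)
        g = _graph(edges)
        k_uv = max_edge_disjoint_paths(g, u, v)
        assert k_uv == max_edge_disjoint_paths(g, v, u)
        deg = Counter()
        for a, b in edges:
            if a != b:
                deg[a] += 1
                deg[b] += 1
        assert k_uv <= min(deg.get(u, 0), deg.get(v, 0))


def test_node_disjoint_variant_is_a_lower_bound():
    rng = np.random.default_rng(13)
    for _ in range(50):
        edges, u, v = _random_instance(rng, max_nodes=6, max_edges=12)
        g = _graph(edges)
        assert (
            max_edge_disjoint_paths(g, u, v, node_disjoint=True)
            <= max_edge_disjoint_paths(g, u, v)
        )
    # parallel edges collapse under node-disjointness (only endpoints shared)
    assert max_edge_disjoint_paths(_graph([(1, 2), (1, 2)]), 1, 2, node_disjoint=True) == 2
    g = _graph([(1, 2), (2, 3), (1, 2), (2, 3)])
    assert max_edge_disjoint_paths(g, 1, 3) == 2
    assert max_edge_disjoint_paths(g, 1, 3, node_disjoint=True) == 1


def test_pairwise_single_edge():
    kappa = pairwise_connectivity(_graph([(2, 3)]))
    assert kappa[1, 2] == kappa[2, 1] == 1
    assert kappa.sum() == 2


def test_pairwise_edgeless():
    assert not pairwise_connectivity(_graph([])).any()


def test_average_connectivity_analytic_cases():
    assert average_connectivity(_graph([])) == 0.0
    assert average_connectivity(_graph([(2, 3)])) == pytest.approx(1 / 276)
    k24 = _graph(
        [(u, v) for u in range(1, 25) for v in range(u + 1, 25)]
    )
    assert average_connectivity(k24) == pytest.approx(23.0)


def test_k4_every_pair_has_three_paths():
    # hand argument: in K4 each pair has the direct edge plus one path
    # through each of the two remaining vertices
    k4 = _graph([(u, v) for u in range(1, 5) for v in range(u + 1, 5)])
    kappa = pairwise_connectivity(k4)
    for u in range(4):
        for v in range(u + 1, 4):
            assert kappa[u, v] == 3


def test_connectivity_lower_bounds_average_connectivity():
    """On connected graphs spanning all 24 nodes, edge connectivity
    (the worst-case pair) cannot exceed the average over pairs."""
    rng = np.random.default_rng(17)
    trials = 0
    while trials < 20:
        G = nx.gnm_random_graph(N_CHROMOSOMES, 40, seed=int(rng.integers(2**31)))
        if not nx.is_connected(G):
            continue
        trials += 1
        edges = [(u + 1, v + 1) for u, v in G.edges()]
        assert nx.edge_connectivity(G) <= average_connectivity(_graph(edges)) + 1e-12


def test_kappa_bar_zero_iff_all_pairs_zero(small_cohort_graphs):
    for g in small_cohort_graphs[:20]:
        kappa = pairwise_connectivity(g)
        kb = average_connectivity(kappa)
        assert (kb == 0) == (not kappa.any())
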