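"""Average graph connectivity of rearrangement multigraphs.

How informative a sample's graph is gets scored by its average connectivity:
the mean, over all C(24,2) = 276 unordered chromosome pairs, of the maximum
number of pairwise edge-disjoint paths joining the pair,

    kappa_bar(G) = sum_{u<v} kappa_G(u, v) / C(p, 2),    p = 24.

kappa_G(u, v) is computed on the symmetrized multigraph (each directed edge
contributes one unit of undirected capacity; parallel edges add capacity) as
unit-capacity maximum flow with BFS augmenting paths, which by Menger's
theorem equals the maximum number of edge-disjoint u-v paths.  Self-loops can
never lie on a u-v path and contribute nothing.

An intra-only graph therefore always has kappa_bar = 0; the filtering stage
scores every sample on its integrated (inter+intra) graph for this reason.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .breakpoints import N_CHROMOSOMES
from .graphs import RearrangementGraph

#: number of unordered chromosome pairs, C(24, 2)
N_PAIRS = N_CHROMOSOMES * (N_CHROMOSOMES - 1) // 2


@dataclass
class ConnectivityProfile:
    """Pairwise disjoint-path counts and the average-connectivity scalar."""

    sample_id: str
    kappa: np.ndarray  # 24x24 symmetric int matrix; diagonal unused
    kappa_bar: float
    p: int = N_CHROMOSOMES


def _undirected_capacity(edges: Sequence[tuple[int, int, str]]) -> dict[int, dict[int, int]]:
    """Symmetrize the edge multiset into undirected unit capacities.

    Self-loops are dropped.  cap[a][b] == cap[b][a] == multiplicity of edges
    between a and b in either direction.
    """
    cap: dict[int, dict[int, int]] = {}
    for u, v, _ in edges:
        if u == v:
            continue
        cap.setdefault(u, {})[v] = cap.get(u, {}).get(v, 0) + 1
        cap.setdefault(v, {})[u] = cap.get(v, {}).get(u, 0) + 1
    return cap


def _max_flow(residual: dict[int, dict[int, int]], s: int, t: int) -> int:
    """Edmonds-Karp on an integer residual network (mutates ``residual``)."""
    flow = 0
    while True:
        # BFS for a shortest augmenting path
        parent: dict[int, int] = {s: s}
        queue = deque([s])
        while queue and t not in parent:
            a = queue.popleft()
            for b, c in residual.get(a, {}).items():
                if c > 0 and b not in parent:
                    parent[b] = a
                    queue.append(b)
        if t not in parent:
            return flow
        # bottleneck along the path
        bottleneck = None
        b = t
        while b != s:
            a = parent[b]
            c = residual[a][b]
            bottleneck = c if bottleneck is None else min(bottleneck, c)
            b = a
        b = t
        while b != s:
            a = parent[b]
            residual[a][b] -= bottleneck
            residual.setdefault(b, {})[a] = residual.get(b, {}).get(a, 0) + bottleneck
            b = a
        flow += bottleneck


def max_edge_disjoint_paths(
    graph: RearrangementGraph | Sequence[tuple[int, int, str]],
    u: int,
    v: int,
    node_disjoint: bool = False,
) -> int:
    """Maximum number of pairwise edge-disjoint u-v paths.

    ``node_disjoint=True`` computes the internally node-disjoint variant
    instead (each intermediate node additionally capped at one path), offered
    for sensitivity analysis; the default matches the edge-disjoint (flow)
    definition used throughout.
    """
    if u == v:
        raise ValueError("endpoints must differ")
    edges = graph.edges if isinstance(graph, RearrangementGraph) else graph
    cap = _undirected_capacity(edges)
    if u not in cap or v not in cap:
        return 0
    if not node_disjoint:
        residual = {a: dict(nbrs) for a, nbrs in cap.items()}
        return _max_flow(residual, u, v)
    # node splitting: w -> (w_in=+w, w_out=-w) with unit internal capacity
    residual: dict[int, dict[int, int]] = {}
    for a, nbrs in cap.items():
        for b, c in nbrs.items():
            residual.setdefault(-a, {})[b] = c
    for w in cap:
        limit = 10**9 if w in (u, v) else 1
        residual.setdefault(w, {})[-w] = limit
    return _max_flow(residual, -u, v)


def brute_force_disjoint_paths(
    graph: RearrangementGraph | Sequence[tuple[int, int, str]],
    u: int,
    v: int,
    max_edges: int = 10,
) -> int:
    """Exhaustive oracle for :func:`max_edge_disjoint_paths` (test-only).

    Enumerates every u-v trail (edge-simple walk) on the symmetrized
    multigraph and recursively packs disjoint trails, returning the largest
    pack.  Exponential; refuses graphs above ``max_edges`` edges.
    """
    if u == v:
        raise ValueError("endpoints must differ")
    edges = graph.edges if isinstance(graph, RearrangementGraph) else graph
    simple = [(a, b) for a, b, _ in edges if a != b]
    if len(simple) > max_edges:
        raise ValueError(f"oracle limited to {max_edges} edges, got {len(simple)}")

    def trails(start: int, used: frozenset[int]) -> list[frozenset[int]]:
        """All edge-index sets of u-v trails avoiding ``used`` edges."""
        found: list[frozenset[int]] = []

        def walk(node: int, used_now: frozenset[int]) -> None:
            if node == v:
                found.append(used_now - used)
                return
            for i, (a, b) in enumerate(simple):
                if i in used_now:
                    continue
                if a == node:
                    walk(b, used_now | {i})
                elif b == node:
                    walk(a, used_now | {i})

        walk(start, used)
        return found

    def pack(used: frozenset[int]) -> int:
        best = 0
        for trail in trails(u, used):
            best = max(best, 1 + pack(used | trail))
        return best

    return pack(frozenset())


def pairwise_connectivity(graph: RearrangementGraph) -> np.ndarray:
    """24x24 matrix of kappa(u, v) over all unordered pairs, mirrored.

    Rows for isolated chromosomes are zero; pairs where either endpoint has
    no incident (non-loop) edge are skipped outright since their flow is 0.
    """
    kappa = np.zeros((N_CHROMOSOMES, N_CHROMOSOMES), dtype=int)
    cap = _undirected_capacity(graph.edges)
    active = sorted(cap)
    for u, v in combinations(active, 2):
        residual = {a: dict(nbrs) for a, nbrs in cap.items()}
        k = _max_flow(residual, u, v)
        kappa[u - 1, v - 1] = k
        kappa[v - 1, u - 1] = k
    return kappa


def average_connectivity(obj: RearrangementGraph | np.ndarray) -> float:
    """kappa_bar: mean disjoint-path count over all 276 unordered pairs."""
    kappa = obj if isinstance(obj, np.ndarray) else pairwise_connectivity(obj)
    iu = np.triu_indices(N_CHROMOSOMES, k=1)
    return float(kappa[iu].sum()) / N_PAIRS


def connectivity_profile(graph: RearrangementGraph) -> ConnectivityProfile:
    kappa = pairwise_connectivity(graph)
    return ConnectivityProfile(
        sample_id=graph.sample_id,
        kappa=kappa,
        kappa_bar=average_connectivity(kappa),
    )


def write_connectivity_report(
    graphs: Sequence[RearrangementGraph],
    profiles: Sequence[ConnectivityProfile],
    path: str | Path,
) -> None:
    """Per-cohort TSV: sample_id, label, n_edges, kappa_bar."""
    by_id = {p.sample_id: p for p in profiles}
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\tn_edges\tkappa_bar\n")
        for g in graphs:
            fh.write(
                f"{g.sample_id}\t{g.label}\t{g.n_edges}\t{by_id[g.sample_id].kappa_bar:.6f}\n"
            )
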