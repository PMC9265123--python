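"""Per-sample rearrangement multigraphs on the 24 human chromosomes.

Every sample becomes one directed multigraph: nodes are the 24 chromosomes
(always all 24, even when isolated), and each aberration contributes one
directed edge from its source chromosome ("Location From") to its sink
chromosome ("Location To").  Intrachromosomal events are self-loops; parallel
edges record repeated aberrations between the same chromosome pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .breakpoints import CRERecord, MUTATION_TYPES, N_CHROMOSOMES, SampleTable

Mode = Literal["inter", "intra", "integrated"]

#: The six typed mutation kinds (everything but "unknown"); used by the
#: richer node-feature scheme for self-loop typing, plus "unknown" = 7 dims.
TYPED_MUTATIONS = MUTATION_TYPES


@dataclass
class RearrangementGraph:
    """A directed multigraph over chromosomes 1..24 with a class label.

    ``edges`` is an ordered multiset of ``(u, v, mutation_type)`` triples;
    order is stable so serialization round-trips losslessly.
    """

    sample_id: str
    label: str
    edges: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_inter(self) -> int:
        return sum(1 for u, v, _ in self.edges if u != v)

    @property
    def n_intra(self) -> int:
        return sum(1 for u, v, _ in self.edges if u == v)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(range(1, N_CHROMOSOMES + 1))
        for u, v, t in self.edges:
            g.add_edge(u, v, mutation_type=t)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {"sample_id": self.sample_id, "label": self.label,
             "edges": [[u, v, t] for u, v, t in self.edges]}
        )

    @classmethod
    def from_json(cls, text: str) -> "RearrangementGraph":
        d = json.loads(text)
        return cls(
            sample_id=d["sample_id"],
            label=d["label"],
            edges=[(int(u), int(v), str(t)) for u, v, t in d["edges"]],
        )


def build_graph(
    sample_id: str,
    label: str,
    records: Sequence[CRERecord],
    mode: Mode = "integrated",
) -> RearrangementGraph:
    """Build one sample's graph, restricted to the requested aberration class.

    ``mode="inter"`` drops self-loops, ``"intra"`` keeps only self-loops,
    ``"integrated"`` keeps everything.  An edgeless graph is legal output.
    """
    edges: list[tuple[int, int, str]] = []
    for rec in records:
        intra = rec.chrom_from == rec.chrom_to
        if mode == "inter" and intra:
            continue
        if mode == "intra" and not intra:
            continue
        edges.append((rec.chrom_from, rec.chrom_to, rec.mutation_type))
    return RearrangementGraph(sample_id=sample_id, label=label, edges=edges)


def build_cohort(table: SampleTable, mode: Mode = "integrated") -> list[RearrangementGraph]:
    """One graph per sample, in sample-table order."""
    return [
        build_graph(sid, label, recs, mode=mode)
        for sid, (label, recs) in table
    ]


def node_features(
    graph: RearrangementGraph,
    scheme: str = "adjacency_row",
) -> np.ndarray:
    """Node-attribute matrix A (24 x d) describing each chromosome's edges.

    ``adjacency_row`` (d=24): row u holds the counts of edges u -> w for every
    chromosome w, so the matrix total equals the edge count.
    ``adjacency_row_plus_types`` (d=31): appends, per chromosome, the 7-dim
    count vector of its self-loop mutation types (typed kinds exist only for
    intrachromosomal events).
    """
    A = np.zeros((N_CHROMOSOMES, N_CHROMOSOMES), dtype=float)
    for u, v, _ in graph.edges:
        A[u - 1, v - 1] += 1.0
    if scheme == "adjacency_row":
        return A
    if scheme == "adjacency_row_plus_types":
        T = np.zeros((N_CHROMOSOMES, len(TYPED_MUTATIONS)), dtype=float)
        type_index = {t: i for i, t in enumerate(TYPED_MUTATIONS)}
        for u, v, t in graph.edges:
            if u == v:
                T[u - 1, type_index[t]] += 1.0
        return np.concatenate([A, T], axis=1)
    raise ValueError(f"unknown feature scheme {scheme!r}")


def to_adjacency_list(graph: RearrangementGraph) -> list[tuple[int, int, str]]:
    """Order-stable, lossless serialization of the edge multiset."""
    return list(graph.edges)


def from_adjacency_list(
    sample_id: str, label: str, edges: Iterable[tuple[int, int, str]]
) -> RearrangementGraph:
    return RearrangementGraph(sample_id, label, [(u, v, t) for u, v, t in edges])


def write_cohort(graphs: Sequence[RearrangementGraph], directory: str | Path) -> Path:
    """Write one JSON document per sample plus a cohort manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in graphs:
        (directory / f"{g.sample_id}.json").write_text(g.to_json() + "\n")
        rows.append((g.sample_id, g.label, g.n_edges, g.n_inter, g.n_intra))
    manifest = directory / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\tlabel\tn_edges\tn_inter\tn_intra\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return manifest


def read_cohort(directory: str | Path) -> list[RearrangementGraph]:
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    graphs = []
    with open(manifest) as fh:
        next(fh)
        for line in fh:
            sid = line.split("\t", 1)[0]
            graphs.append(
                RearrangementGraph.from_json((directory / f"{sid}.json").read_text())
            )
    return graphs
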