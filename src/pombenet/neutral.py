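"""Neutral graph over functional genotypes.

The neutral graph is a metagraph: each node is a functional network
(a genotype), and two nodes are joined by an undirected edge when their
genotypes sit at Hamming distance one, i.e. differ in exactly one parameter.
Connected components of this graph describe how far the wildtype can drift by
single-parameter mutations without losing the cell-cycle trajectory.

By default the Hamming distance is taken over the concatenated genotype
(all W entries plus all Θ entries), since the mutation operator edits both;
``mode="matrix_only"`` restricts it to the weight matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .evolution import Genotype

__all__ = [
    "genotype_distance",
    "NeutralGraph",
    "build_graph",
    "wildtype_component",
    "distance_profile",
    "export_graphml",
    "export_edge_list",
]

_MODES = ("concatenated", "matrix_only")


def _vectorize(genotypes: list[Genotype], mode: str) -> np.ndarray:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    rows = []
    for g in genotypes:
        v = g.W.ravel() if mode == "matrix_only" else np.concatenate([g.W.ravel(), g.theta2])
        rows.append(v)
    return np.vstack(rows)


def genotype_distance(g1: Genotype, g2: Genotype, mode: str = "concatenated") -> int:
    """Number of parameters at which two genotypes differ (a metric)."""
    if g1.W.shape != g2.W.shape or g1.theta2.shape != g2.theta2.shape:
        raise ValueError("genotypes have different dimensions")
    d = int((g1.W != g2.W).sum())
    if mode == "concatenated":
        d += int((g1.theta2 != g2.theta2).sum())
    elif mode != "matrix_only":
        raise ValueError(f"mode must be one of {_MODES}")
    return d


@dataclass(frozen=True)
class NeutralGraph:
    """The metagraph: genotypes as nodes, edges at Hamming distance 1."""

    graph: nx.Graph
    genotypes: tuple[Genotype, ...]
    wildtype_index: int
    mode: str

    @property
    def n_nodes(self) -> int:
        return len(self.genotypes)

    def components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_graph(
    collection: list[Genotype],
    wildtype: Genotype,
    mode: str = "concatenated",
    chunk: int = 512,
) -> NeutralGraph:
    """All-pairs construction of the neutral graph.

    ``collection`` must be deduplicated; the wildtype is inserted if absent.
    Pairwise distances are computed in chunks (O(N²·n²) overall, fine for the
    ~10⁴ genotypes of a full harvest at n = 10).
    """
    genotypes = list(collection)
    keys = [g.key() for g in genotypes]
    if len(set(keys)) != len(keys):
        raise ValueError("collection contains duplicate genotypes")
    try:
        wt_idx = keys.index(wildtype.key())
    except ValueError:
        genotypes.append(wildtype)
        wt_idx = len(genotypes) - 1
    vec = _vectorize(genotypes, mode)
    G = nx.Graph()
    G.add_nodes_from(range(len(genotypes)))
    for start in range(0, len(genotypes), chunk):
        block = vec[start : start + chunk]
        # distances from this chunk to all later genotypes (upper triangle)
        diff = (block[:, None, :] != vec[None, :, :]).sum(axis=2)
        for a, b in zip(*np.nonzero(diff == 1)):
            i, j = start + int(a), int(b)
            if i < j:
                G.add_edge(i, j)
    return NeutralGraph(graph=G, genotypes=tuple(genotypes), wildtype_index=wt_idx, mode=mode)


def wildtype_component(ng: NeutralGraph) -> set[int]:
    """Node indices of the connected component containing the wildtype."""
    return set(nx.node_connected_component(ng.graph, ng.wildtype_index))


def distance_profile(ng: NeutralGraph):
    """Per-node distances to the wildtype, plus per-group summaries.

    Returns a ``(per_node, summary)`` pair of DataFrames.  Inside the
    wildtype component, ``path_length`` is the exact BFS shortest-path length
    (each edge is one parameter change); outside it is infinite, and the raw
    genotype distance is what remains comparable.
    """
    import pandas as pd

    wt = ng.genotypes[ng.wildtype_index]
    comp = wildtype_component(ng)
    lengths = nx.single_source_shortest_path_length(ng.graph, ng.wildtype_index)
    rows = []
    for i, g in enumerate(ng.genotypes):
        rows.append(
            {
                "node": i,
                "in_component": i in comp,
                "path_length": float(lengths.get(i, math.inf)),
                "genotype_distance": genotype_distance(g, wt, ng.mode),
            }
        )
    per_node = pd.DataFrame(rows)
    summary = (
        per_node.groupby("in_component")["genotype_distance"]
        .agg(["count", "min", "median", "max"])
        .reset_index()
    )
    return per_node, summary


def export_graphml(ng: NeutralGraph, path, node_attrs: dict[int, dict] | None = None) -> None:
    """Write the metagraph as GraphML with per-node metadata attributes."""
    G = nx.Graph()
    for i in range(ng.n_nodes):
        attrs = {"genotype_id": i, "is_wildtype": i == ng.wildtype_index}
        if node_attrs and i in node_attrs:
            attrs.update(node_attrs[i])
        G.add_node(i, **attrs)
    G.add_edges_from(ng.graph.edges)
    nx.write_graphml(G, path)


def export_edge_list(ng: NeutralGraph, path) -> None:
    """Plain TSV edge list (one undirected edge per row)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(ng.graph.edges):
            fh.write(f"{u}\t{v}\n")
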