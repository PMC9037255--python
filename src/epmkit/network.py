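"""Background gene-interaction network.

Edges are undirected and stored canonically (lexicographically smaller gene
first); the canonical orientation fixes the sign convention of the delta rank
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._util import canonical_edge, json_dumps_stable


@dataclass(frozen=True)
class InteractionNetwork:
    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...]  # canonical, sorted, unique
    degree: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def summary_json(self) -> str:
        hist: dict[int, int] = {}
        for d in self.degree.values():
            hist[d] = hist.get(d, 0) + 1
        return json_dumps_stable(
            {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "degree_histogram": {str(k): v for k, v in sorted(hist.items())},
            }
        )


def build_network(raw_edges: Iterable[tuple[str, str]]) -> InteractionNetwork:
    """Canonicalize an edge list: drop self-loops, dedupe (A,B)/(B,A)."""
    edge_set = {canonical_edge(a, b) for a, b in raw_edges if a != b}
    if not edge_set:
        raise ValueError("edge set is empty after removing self-loops")
    edges = tuple(sorted(edge_set))
    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    return InteractionNetwork(frozenset(degree), edges, degree)


def restrict_to_genes(net: InteractionNetwork, genes: Iterable[str]) -> InteractionNetwork:
    """Keep only edges with both endpoints in ``genes``; isolated nodes drop."""
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    kept = [e for e in net.edges if e[0] in genes and e[1] in genes]
    if not kept:
        raise ValueError("no edge survives the gene restriction")
    return build_network(kept)


def rank_nodes_by_degree(net: InteractionNetwork) -> list[tuple[str, int]]:
    """Nodes sorted by descending degree; ties broken by gene id ascending."""
    return sorted(net.degree.items(), key=lambda kv: (-kv[1], kv[0]))
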