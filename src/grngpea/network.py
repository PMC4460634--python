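"""Undirected simple-graph container shared by every pipeline stage.

Edges are stored under a canonical key ``(a, b)`` with ``a < b``
lexicographically; all set operations across the package rely on this
canonical form.  Each edge carries a weight (the ensemble consensus rate
for BC3Net networks, a dependency score for relevance networks, 1.0 for
plain edge lists) and an optional adjusted p-value.

Nodes are tracked explicitly and independently of edges so that a network
inferred from an expression matrix remembers its full gene universe even
when most genes end up isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import DataError

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the canonical (lexicographically sorted) form of an edge.

    Raises :class:`DataError` for self-loops: the networks handled here
    are simple graphs.
    """
    if a == b:
        raise DataError(f"self-loop not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class EdgeData:
    """Attributes of one undirected edge."""

    weight: float = 1.0
    pvalue_adj: float | None = None


class Network:
    """Undirected simple graph with weighted edges and an explicit node set.

    Parameters
    ----------
    nodes:
        Initial node universe (edges may only touch known nodes after
        ``strict`` adds; by default endpoints are added implicitly).
    B:
        Ensemble size the edge weights refer to (1 for single networks).
    """

    def __init__(self, nodes: Iterable[str] = (), B: int = 1):
        self._nodes: set[str] = set(nodes)
        self._edges: dict[Edge, EdgeData] = {}
        self.B = int(B)

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._nodes.add(node)

    def add_edge(
        self,
        a: str,
        b: str,
        weight: float = 1.0,
        pvalue_adj: float | None = None,
        merge: str = "max",
    ) -> None:
        """Add an undirected edge; duplicates merge by keeping max weight."""
        key = canonical_edge(a, b)
        self._nodes.add(a)
        self._nodes.add(b)
        existing = self._edges.get(key)
        if existing is None or merge == "replace" or weight > existing.weight:
            self._edges[key] = EdgeData(weight=weight, pvalue_adj=pvalue_adj)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        nodes: Iterable[str] = (),
        B: int = 1,
    ) -> "Network":
        net = cls(nodes=nodes, B=B)
        for a, b in edges:
            net.add_edge(a, b)
        return net

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._nodes))

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> Mapping[Edge, EdgeData]:
        return self._edges

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self._edges

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges)

    def degree(self) -> dict[str, int]:
        deg = {node: 0 for node in self._nodes}
        for a, b in self._edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    # -- derived graphs ----------------------------------------------
    def induced_subgraph(self, genes: Iterable[str]) -> "Network":
        """Subgraph on ``genes`` (nodes restricted, edges with both ends in)."""
        keep = set(genes) & self._nodes
        sub = Network(nodes=keep, B=self.B)
        for (a, b), data in self._edges.items():
            if a in keep and b in keep:
                sub._edges[(a, b)] = EdgeData(data.weight, data.pvalue_adj)
        return sub

    def relabel(self, mapping: Mapping[str, str]) -> "Network":
        """Return a copy with node labels replaced via ``mapping``."""
        out = Network(nodes=(mapping.get(v, v) for v in self._nodes), B=self.B)
        for (a, b), data in self._edges.items():
            out.add_edge(
                mapping.get(a, a), mapping.get(b, b), data.weight, data.pvalue_adj
            )
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for (a, b), data in self._edges.items():
            g.add_edge(a, b, weight=data.weight, pvalue_adj=data.pvalue_adj)
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges}, B={self.B})"
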