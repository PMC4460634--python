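"""Structural network characterization.

Degree centrality (neighbor counts and hub tables), edge density, giant
connected component, discrete power-law exponent of the degree
distribution, and mean shortest-path length on the giant component.
Edges are unweighted here, so shortest paths are plain BFS distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, special

from .errors import ConfigError, DataError
from .network import Network

__all__ = [
    "NetworkSummary",
    "degree_centrality",
    "hub_table",
    "edge_density",
    "powerlaw_exponent",
    "avg_shortest_path",
    "giant_component",
    "summarize",
]


def degree_centrality(net: Network) -> dict[str, int]:
    """Neighbor count per node (simple graph)."""
    return net.degree()


def hub_table(net: Network, k: int = 25) -> list[tuple[str, int]]:
    """Top-k genes by degree; deterministic order (degree desc, id asc)."""
    deg = net.degree()
    ranked = sorted(deg.items(), key=lambda t: (-t[1], t[0]))
    return ranked[:k]


def edge_density(net: Network) -> float:
    """Edges over the n(n-1)/2 possible pairs; 0 for graphs with < 2 nodes."""
    n = net.n_nodes
    if n < 2:
        return 0.0
    return net.n_edges / (n * (n - 1) / 2)


def powerlaw_exponent(
    degrees, xmin: int = 1, method: str = "mle"
) -> float:
    """Exponent of a discrete power law fitted to degrees >= xmin.

    ``method="mle"`` (default) maximizes the truncated zeta likelihood
    P(d) = d^-alpha / zeta(alpha, xmin) numerically (Hurwitz zeta);
    ``method="approx"`` uses the continuous approximation
    alpha = 1 + n / sum(ln(d_i / (xmin - 0.5))), adequate only for large
    xmin.  Requires at least 50 degrees >= max(1, xmin); all-equal
    degrees are an estimation error.
    """
    d = np.asarray([x for x in degrees if x >= max(1, xmin)], dtype=float)
    if d.size < 50:
        raise DataError(f"need >= 50 degrees >= xmin, got {d.size}")
    if np.all(d == d[0]):
        raise DataError("all degrees equal; exponent not estimable")
    if method == "approx":
        return float(1.0 + d.size / np.sum(np.log(d / (xmin - 0.5))))
    if method != "mle":
        raise ConfigError(f"unknown method {method!r}")
    mean_log = float(np.mean(np.log(d)))

    def negloglik(alpha: float) -> float:
        return alpha * mean_log + float(np.log(special.zeta(alpha, xmin)))

    res = optimize.minimize_scalar(negloglik, bounds=(1.05, 30.0), method="bounded")
    return float(res.x)


def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member node.
    """
    if net.n_nodes == 0:
        raise DataError("empty network")
    g = net.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return net.induced_subgraph(comps[0])


def avg_shortest_path(
    net: Network,
    exact_max_nodes: int = 2000,
    n_sources: int = 64,
    seed: int = 0,
) -> float:
    """Mean BFS distance over node pairs of the giant component.

    Exact (all-pairs BFS) up to ``exact_max_nodes`` nodes; above that the
    mean is estimated from ``n_sources`` uniformly sampled (seeded)
    source nodes, averaging distances to all other nodes — an unbiased
    estimator of the pairwise mean.
    """
    gcc = giant_component(net)
    g = gcc.to_networkx()
    n = g.number_of_nodes()
    if n < 2:
        raise DataError("giant component has fewer than 2 nodes")
    if n <= exact_max_nodes:
        return float(nx.average_shortest_path_length(g))
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    sources = rng.choice(len(nodes), size=min(n_sources, n), replace=False)
    total = 0.0
    count = 0
    for si in sources:
        lengths = nx.single_source_shortest_path_length(g, nodes[si])
        total += sum(lengths.values())  # self-distance contributes 0
        count += len(lengths) - 1
    return total / count


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    gcc_size: int
    powerlaw_alpha: float | None
    avg_path_length: float | None
    degrees: dict[str, int] = field(repr=False, default_factory=dict)


def summarize(net: Network, xmin: int = 1, seed: int = 0) -> NetworkSummary:
    """One-stop structural summary; alpha/path are None when not estimable."""
    deg = net.degree()
    try:
        alpha = powerlaw_exponent(deg.values(), xmin=xmin)
    except DataError:
        alpha = None
    try:
        apl = avg_shortest_path(net, seed=seed)
    except DataError:
        apl = None
    gcc = giant_component(net) if net.n_nodes else None
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=edge_density(net),
        gcc_size=gcc.n_nodes if gcc else 0,
        powerlaw_alpha=alpha,
        avg_path_length=apl,
        degrees=deg,
    )
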