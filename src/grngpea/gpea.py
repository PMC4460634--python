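"""Gene-pair enrichment analysis (GPEA).

For a network on p genes there are N = p(p-1)/2 gene pairs; a gene set S
with p_S member genes in the network contributes m_S = p_S(p_S-1)/2 of
them.  If the network has n edges, of which k fall within S, the
enrichment p-value is the hypergeometric upper tail

    p(k | S) = sum_{i=k}^{m_S} C(m_S, i) C(N - m_S, n - i) / C(N, n),

the probability of observing k or more edges among the pairs of S when n
edges are placed uniformly among the N pairs.  A secondary enrichment
asks whether the genes of a significant subnetwork are over-represented
for a curated census gene list (gene-based hypergeometric test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .errors import ConfigError, DataError
from .genesets import GeneSetCollection
from .network import Edge, Network

__all__ = ["GPEAResult", "gpea_pvalue", "run_gpea", "census_enrichment"]


def gpea_pvalue(k: int, m_S: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k) for edges within a gene set.

    Population: N gene pairs, of which m_S lie within the set; n draws
    (network edges); k observed within-set edges.  ``k = 0`` returns 1
    exactly.
    """
    if not (0 <= m_S <= N):
        raise DataError(f"require 0 <= m_S <= N, got m_S={m_S}, N={N}")
    if not (0 <= n <= N):
        raise DataError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= m_S):
        raise DataError(f"require 0 <= k <= m_S, got k={k}, m_S={m_S}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); clip away negative round-off
    p = float(stats.hypergeom.sf(k - 1, N, m_S, n))
    return min(1.0, max(p, 0.0))


@dataclass
class GPEAResult:
    """Per-set enrichment record (symbols as in the tail formula above)."""

    set_name: str
    p_genes: int  # universe size p (network node count)
    N: int  # p(p-1)/2
    p_S: int  # effective set size after universe intersection
    m_S: int  # p_S(p_S-1)/2
    n_edges: int  # network edge count n
    k: int  # within-set edge count
    p_raw: float
    p_adj: float
    subnetwork: list[Edge] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_adj <= 0.001


def run_gpea(
    net: Network,
    sets: GeneSetCollection,
    alpha: float = 0.001,
    correction: str = "bonferroni",
) -> list[GPEAResult]:
    """GPEA over a gene-set collection; results sorted by adjusted p-value.

    The gene universe is the network node set: sets are intersected with
    it and sets left with fewer than 2 member genes (no testable pair)
    are excluded.  ``correction`` is ``bonferroni`` (p_adj = min(1, p*T)
    over the T tested sets) or ``fdr`` (Benjamini-Hochberg).
    """
    if correction not in ("bonferroni", "fdr"):
        raise ConfigError(f"unknown correction {correction!r}")
    universe = net.node_set
    p = len(universe)
    N = p * (p - 1) // 2
    n = net.n_edges
    tested: list[tuple[str, frozenset[str], int, list[Edge]]] = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        if len(members) < 2:
            continue
        sub = [e for e in net.edges() if e[0] in members and e[1] in members]
        tested.append((name, members, len(sub), sub))
    if not tested:
        raise DataError("no testable gene sets after universe intersection")
    T = len(tested)
    raws = []
    for name, members, k, sub in tested:
        m_S = len(members) * (len(members) - 1) // 2
        raws.append(gpea_pvalue(k, m_S, n, N))
    if correction == "bonferroni":
        adjs = [min(1.0, pr * T) for pr in raws]
    else:
        from statsmodels.stats.multitest import multipletests

        adjs = list(multipletests(raws, method="fdr_bh")[1])
    results = []
    for (name, members, k, sub), p_raw, p_adj in zip(tested, raws, adjs):
        p_S = len(members)
        results.append(
            GPEAResult(
                set_name=name,
                p_genes=p,
                N=N,
                p_S=p_S,
                m_S=p_S * (p_S - 1) // 2,
                n_edges=n,
                k=k,
                p_raw=p_raw,
                p_adj=float(p_adj),
                subnetwork=sorted(sub),
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.set_name))
    return results


def census_enrichment(
    results: list[GPEAResult],
    census: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> list[tuple[str, float, list[str]]]:
    """Secondary census-gene enrichment of GPEA subnetworks.

    For each result, the sample is the genes incident to at least one
    subnetwork edge; successes are census members within ``universe``
    (the network node set).  Returns (set_name, p-value, census genes in
    the subnetwork) per result, in input order.
    """
    census = frozenset(census)
    universe = frozenset(universe)
    if not census:
        raise DataError("empty census gene list")
    K = len(census & universe)
    U = len(universe)
    out = []
    for res in results:
        subgenes: set[str] = set()
        for a, b in res.subnetwork:
            subgenes.add(a)
            subgenes.add(b)
        s = len(subgenes)
        hits = sorted(subgenes & census)
        x = len(hits)
        if x == 0 or s == 0:
            pval = 1.0
        else:
            pval = min(1.0, max(float(stats.hypergeom.sf(x - 1, U, K, s)), 0.0))
        out.append((res.set_name, pval, hits))
    return out
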