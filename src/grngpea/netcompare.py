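"""Network-vs-network quantification.

Shared-edge overlaps (pairwise and triple), the hypergeometric
shared-edge test, confusion-matrix metrics (TP/FP/TN/FN, precision,
recall, F-score) against a reference network globally and per gene-set
subnetwork, and gene-label-randomized baselines that calibrate how much
agreement is expected by chance.

The comparison universe defaults to the intersection of the two node
sets so that coverage differences are not conflated with disagreement;
pass ``universe="union"`` (or an explicit gene list) for the global
union-style comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .genesets import GeneSetCollection
from .gpea import gpea_pvalue
from .network import Edge, Network


@dataclass
class ComparisonMetrics:
    """Confusion counts and derived scores for one comparison.

    ``TP + FP + TN + FN`` always equals C(u, 2) for the u genes of the
    comparison universe; F = 2PR/(P+R), defined as 0 when P + R = 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _resolve_universe(
    net: Network, ref: Network, universe: str | Iterable[str] | None
) -> frozenset[str]:
    if universe is None or universe == "intersection":
        uni = net.node_set & ref.node_set
    elif universe == "union":
        uni = net.node_set | ref.node_set
    else:
        uni = frozenset(universe)
    if not uni:
        raise DataError("empty comparison universe")
    return frozenset(uni)


def _edges_in(net: Network, uni: frozenset[str]) -> frozenset[Edge]:
    return frozenset(e for e in net.edges() if e[0] in uni and e[1] in uni)


def edge_overlap(
    nets: Sequence[Network],
) -> tuple[frozenset[Edge], float]:
    """Shared edges and shared fraction over the union, for 2 or 3 networks.

    Edges are restricted to the shared node universe; for 3 networks the
    fraction is the triple intersection over the triple union.
    """
    if len(nets) not in (2, 3):
        raise ConfigError("edge_overlap takes 2 or 3 networks")
    uni = frozenset.intersection(*(n.node_set for n in nets))
    edge_sets = [_edges_in(n, uni) for n in nets]
    union = frozenset.union(*edge_sets)
    if not union:
        raise DataError("empty edge union on the shared node universe")
    shared = frozenset.intersection(*edge_sets)
    return shared, len(shared) / len(union)


def shared_edge_test(
    net_a: Network, net_b: Network, universe: str | Iterable[str] | None = None
) -> float:
    """Hypergeometric upper-tail p for the number of shared edges.

    Population C(u, 2) pairs, successes |E_a|, draws |E_b|, observed
    |E_a intersect E_b| — the same tail kernel as the GPEA p-value, and
    symmetric in the two networks.
    """
    uni = _resolve_universe(net_a, net_b, universe)
    u = len(uni)
    n_pairs = u * (u - 1) // 2
    ea = _edges_in(net_a, uni)
    eb = _edges_in(net_b, uni)
    if len(ea) > n_pairs or len(eb) > n_pairs:
        raise DataError("edge count exceeds the pair space")
    return gpea_pvalue(k=len(ea & eb), m_S=len(ea), n=len(eb), N=n_pairs)


def confusion_vs_reference(
    net: Network, ref: Network, universe: str | Iterable[str] | None = None
) -> ComparisonMetrics:
    """TP/FP/TN/FN of ``net`` against reference ``ref`` over the universe."""
    uni = _resolve_universe(net, ref, universe)
    u = len(uni)
    n_pairs = u * (u - 1) // 2
    e_net = _edges_in(net, uni)
    e_ref = _edges_in(ref, uni)
    tp = len(e_net & e_ref)
    fp = len(e_net - e_ref)
    fn = len(e_ref - e_net)
    tn = n_pairs - tp - fp - fn
    return ComparisonMetrics(TP=tp, FP=fp, TN=tn, FN=fn)


def subnetwork_fscores(
    net: Network,
    ref: Network,
    sets: GeneSetCollection,
    universe: str | Iterable[str] | None = None,
) -> tuple[dict[str, ComparisonMetrics], list[str]]:
    """Per-set comparison of induced subgraphs of ``net`` and ``ref``.

    Sets whose induced reference subgraph has no edges are skipped (a
    comparison against an empty reference is uninformative) and returned
    in the second element.
    """
    metrics: dict[str, ComparisonMetrics] = {}
    skipped: list[str] = []
    for name in sorted(sets.sets):
        members = sets.sets[name]
        sub_ref = ref.induced_subgraph(members)
        if sub_ref.n_edges == 0:
            skipped.append(name)
            continue
        sub_net = net.induced_subgraph(members)
        metrics[name] = confusion_vs_reference(sub_net, sub_ref, universe=universe)
    return metrics, skipped


def randomized_label_baseline(
    net: Network,
    ref: Network,
    sets: GeneSetCollection | None,
    reps: int = 25,
    seed: int = 0,
    identity: bool = False,
) -> dict:
    """Gene-label-randomized baseline F-score distribution.

    Per repetition, the reference's node labels are uniformly permuted
    (within its node set) and the comparison recomputed.  With ``sets``
    the per-set F-scores are pooled and per-set means returned; with
    ``sets=None`` the global F-score against the relabeled reference is
    computed instead.  ``identity=True`` is a test hook that applies the
    identity permutation every repetition.  Deterministic under ``seed``.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = sorted(ref.node_set)
    per_rep_f: list[float] = []
    per_set_f: dict[str, list[float]] = {}
    for _ in range(reps):
        if identity:
            mapping = {v: v for v in labels}
        else:
            perm = rng.permutation(len(labels))
            mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}
        ref_r = ref.relabel(mapping)
        if sets is None:
            per_rep_f.append(confusion_vs_reference(net, ref_r).fscore)
        else:
            metrics, _ = subnetwork_fscores(net, ref_r, sets)
            fs = [m.fscore for m in metrics.values()]
            per_rep_f.append(float(np.mean(fs)) if fs else 0.0)
            for name, m in metrics.items():
                per_set_f.setdefault(name, []).append(m.fscore)
    return {
        "per_rep_mean_f": per_rep_f,
        "mean_f": float(np.mean(per_rep_f)),
        "per_set_mean_f": {k: float(np.mean(v)) for k, v in sorted(per_set_f.items())},
        "pooled_f": [f for v in per_set_f.values() for f in v]
        if sets is not None
        else list(per_rep_f),
    }
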