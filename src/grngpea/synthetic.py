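"""Synthetic ground truth for the whole pipeline.

Real tumor expression datasets give no access to the true regulatory
network, so this module plants one: a scale-free undirected graph is
realized as a Gaussian graphical model (GGM) and expression is sampled
from it, optionally pushed through an RNAseq-count-like or
array-intensity-like observation layer.  Under a GGM the planted edges
are the strongest pairwise dependencies, which is exactly the regime the
C3Net/BC3Net maximal-dependency rule is designed to detect; planted
connected subgraphs give the gene-pair enrichment analysis a signal to
find, contiguous genomic placement of some of those subgraphs gives the
co-location window sets a signal, and a partially rewired copy of the
truth stands in for a public protein-interaction reference.

Every generator is a pure function of its parameters and a single
integer seed; the seed fans out to per-stage child streams through fixed
stage tags so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import linalg

from .errors import ConfigError, GenerationError
from .genesets import GeneSetCollection
from .io_formats import ExpressionMatrix
from .network import Edge, Network, canonical_edge

# fixed per-stage child-seed tags
_STAGE_GRN = 11
_STAGE_EXPR = 23
_STAGE_SETS = 37
_STAGE_ANN = 53
_STAGE_REF = 71

DIAG_MARGIN = 0.1
"""Diagonal-dominance margin of the precision matrix: guarantees positive
definiteness while keeping draws away from singularity."""


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


@dataclass
class PlantedGRN:
    """Ground-truth dependency network.

    ``edge_strength`` values live on the partial-correlation scale: they
    enter the precision matrix of the GGM as negative off-diagonals.
    """

    nodes: tuple[str, ...]
    edges: dict[Edge, float] = field(repr=False)  # edge -> strength
    target_exponent: float = 4.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_network(self) -> Network:
        net = Network(nodes=self.nodes, B=1)
        for (a, b), s in self.edges.items():
            net.add_edge(a, b, weight=float(abs(s)))
        return net


def make_planted_grn(
    p: int,
    exponent: float = 4.0,
    seed: int = 0,
    strength_range: tuple[float, float] = (0.2, 0.4),
    min_degree: int = 2,
    max_degree: int | None = None,
    max_retries: int = 50,
) -> PlantedGRN:
    """Scale-free simple graph via a power-law configuration model.

    Degrees are drawn from a truncated discrete power law
    P(d) ~ d^-exponent on [min_degree, max_degree] and realized with a
    configuration model; self-loops and multi-edges are discarded.  The
    minimum degree defaults to 2, which keeps the model supercritical so
    the giant component covers >= 90% of nodes (with minimum degree 1 a
    power law steeper than ~3.5 has no giant component at all).  Retries
    with fresh degree sequences until the giant-component constraint
    holds; deterministic under ``seed``.
    """
    if p < 20:
        raise ConfigError("p must be >= 20")
    if exponent <= 2:
        raise ConfigError("exponent must be > 2")
    if max_degree is None:
        max_degree = max(min_degree + 2, int(round(p**0.5)))
    rng = _rng(seed, _STAGE_GRN)
    support = np.arange(min_degree, max_degree + 1)
    pmf = support.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    nodes = tuple(f"G{i:04d}" for i in range(p))
    for _ in range(max_retries):
        degrees = rng.choice(support, size=p, p=pmf)
        if degrees.sum() % 2 == 1:
            bump = int(rng.integers(0, p))
            degrees[bump] += 1 if degrees[bump] < max_degree else -1
        g = nx.configuration_model(
            degrees.tolist(), seed=int(rng.integers(0, 2**31 - 1))
        )
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        gcc = max(nx.connected_components(g), key=len)
        if len(gcc) >= 0.9 * p:
            edges: dict[Edge, float] = {}
            lo, hi = strength_range
            for i, j in sorted(tuple(sorted((int(a), int(b)))) for a, b in g.edges):
                edges[canonical_edge(nodes[i], nodes[j])] = float(
                    rng.uniform(lo, hi)
                )
            return PlantedGRN(nodes=nodes, edges=edges, target_exponent=exponent)
    raise GenerationError(
        f"no degree sequence with a >=90% giant component after {max_retries} tries"
    )


def simulate_expression(
    truth: PlantedGRN,
    n: int,
    platform: str = "rnaseq",
    noise_sd: float = 0.1,
    seed: int = 0,
    count_scale: float = 0.7,
    count_offset: float = 3.0,
) -> ExpressionMatrix:
    """Sample expression from the GGM implied by ``truth``.

    The precision matrix has -strength on planted edges and a
    diagonally dominant diagonal (row sum of |off-diagonals| plus
    ``DIAG_MARGIN``), hence is positive definite by construction.  Latent
    profiles are standardized to unit marginal variance and mapped to the
    observation scale: ``rnaseq`` rounds exp(a*z + b) to counts and
    returns log1p(counts); ``array`` adds Gaussian measurement noise of
    sd ``noise_sd``.  Deterministic under ``seed``.
    """
    if n < 10:
        raise ConfigError("n must be >= 10")
    if platform not in ("rnaseq", "array"):
        raise ConfigError(f"unknown platform {platform!r}")
    rng = _rng(seed, _STAGE_EXPR)
    p = truth.n_nodes
    index = {g: i for i, g in enumerate(truth.nodes)}
    omega = np.zeros((p, p))
    for (a, b), s in truth.edges.items():
        omega[index[a], index[b]] = -s
        omega[index[b], index[a]] = -s
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + DIAG_MARGIN)
    try:
        chol = linalg.cholesky(omega, lower=False)  # omega = U^T U
    except linalg.LinAlgError as exc:  # pragma: no cover - excluded by construction
        raise AssertionError("precision matrix not positive definite") from exc
    # x = U^-1 e has covariance omega^-1
    e = rng.standard_normal((p, n))
    z = linalg.solve_triangular(chol, e, lower=False)
    sigma_diag = np.diag(linalg.cho_solve((chol, False), np.eye(p)))
    z = z / np.sqrt(sigma_diag)[:, None]
    if platform == "rnaseq":
        counts = np.rint(np.exp(count_scale * z + count_offset))
        values = np.log1p(counts)
    else:
        values = z + rng.normal(0.0, noise_sd, size=z.shape)
    samples = [f"S{i:03d}" for i in range(n)]
    return ExpressionMatrix(list(truth.nodes), samples, values)


def plant_gene_sets(
    truth: PlantedGRN,
    k_true: int = 10,
    k_null: int = 10,
    size_range: tuple[int, int] = (8, 15),
    seed: int = 0,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Plant connected "true" gene sets and size-matched random null sets.

    True sets are vertex sets of BFS-grown connected subgraphs of the
    truth, pairwise disjoint (so they can later be laid out contiguously
    on a chromosome); null sets are uniform random gene samples of the
    same sizes.  Set sizes are uniform in ``size_range``.
    """
    rng = _rng(seed, _STAGE_SETS)
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ConfigError("invalid size_range")
    g = nx.Graph(list(truth.edges))
    g.add_nodes_from(truth.nodes)
    gcc = max(nx.connected_components(g), key=len) if truth.n_edges else set()
    if hi > len(gcc):
        raise GenerationError("size_range exceeds the giant component")
    used: set[str] = set()
    true_sets: dict[str, frozenset[str]] = {}
    sizes: list[int] = []
    for t in range(k_true):
        size = int(rng.integers(lo, hi + 1))
        sizes.append(size)
        grown = _grow_connected(g, gcc - used, size, rng)
        if grown is None:
            raise GenerationError(
                f"could not grow disjoint connected set {t} of size {size}"
            )
        used |= grown
        true_sets[f"true_{t:02d}"] = frozenset(grown)
    null_sets: dict[str, frozenset[str]] = {}
    all_nodes = list(truth.nodes)
    for t in range(k_null):
        size = sizes[t] if t < len(sizes) else int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(all_nodes), size=size, replace=False)
        null_sets[f"null_{t:02d}"] = frozenset(all_nodes[i] for i in pick)
    return (
        GeneSetCollection(sets=true_sets, kind="functional",
                          descriptions={k: "planted connected subgraph" for k in true_sets}),
        GeneSetCollection(sets=null_sets, kind="functional",
                          descriptions={k: "size-matched random set" for k in null_sets}),
    )


def _grow_connected(
    g: nx.Graph, available: set[str], size: int, rng: np.random.Generator
) -> set[str] | None:
    """BFS-grow a connected subgraph of ``size`` nodes inside ``available``."""
    pool = sorted(available)
    if len(pool) < size:
        return None
    for _ in range(200):
        start = pool[int(rng.integers(0, len(pool)))]
        visited = {start}
        frontier = [start]
        while frontier and len(visited) < size:
            node = frontier.pop(0)
            for nb in sorted(g.neighbors(node)):
                if nb in available and nb not in visited:
                    visited.add(nb)
                    frontier.append(nb)
                    if len(visited) >= size:
                        break
        if len(visited) >= size:
            return visited
    return None


def plant_annotation(
    truth: PlantedGRN,
    genesets_true: GeneSetCollection,
    colocate_fraction: float = 0.5,
    spacing_bp: int = 100_000,
    seed: int = 0,
    n_chromosomes: int = 5,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    gene_length: int = 1_000,
):
    """Lay genes on synthetic chromosomes; co-locate a fraction of true sets.

    A ``colocate_fraction`` of the true sets is placed contiguously: each
    chosen set starts at a step-boundary coordinate and its members are
    spaced so the whole block spans less than one window, hence falls
    inside a single ``window_bp`` window.  All remaining genes are
    shuffled and laid out with ``spacing_bp`` between starts across
    ``n_chromosomes`` chromosomes.

    Returns ``(annotation, colocated_set_names)``.
    """
    if not (0.0 <= colocate_fraction <= 1.0):
        raise ConfigError("colocate_fraction must be in [0, 1]")
    rng = _rng(seed, _STAGE_ANN)
    set_names = sorted(genesets_true.sets)
    n_colocate = int(round(colocate_fraction * len(set_names)))
    chosen = sorted(
        set_names[i]
        for i in rng.choice(len(set_names), size=n_colocate, replace=False)
    ) if n_colocate else []
    colocated_genes: set[str] = set()
    blocks: list[list[str]] = []
    for name in chosen:
        members = sorted(genesets_true.sets[name])
        blocks.append(members)
        colocated_genes |= set(members)
    rest = [g for g in truth.nodes if g not in colocated_genes]
    perm = rng.permutation(len(rest))
    rest = [rest[i] for i in perm]

    records = []
    per_chrom = -(-truth.n_nodes // n_chromosomes)  # ceil
    chrom_idx, placed_on_chrom, cursor = 0, 0, 0

    def next_chrom_if_full():
        nonlocal chrom_idx, placed_on_chrom, cursor
        if placed_on_chrom >= per_chrom and chrom_idx < n_chromosomes - 1:
            chrom_idx += 1
            placed_on_chrom = 0
            cursor = 0

    for block in blocks:
        next_chrom_if_full()
        # align block start to a step boundary -> one window holds it all
        cursor = -(-cursor // step_bp) * step_bp
        if cursor % window_bp == 0 and cursor > 0:
            cursor += step_bp  # keep a gap from the previous occupants
        block_spacing = min(spacing_bp, (window_bp - gene_length - 1) // max(1, len(block)))
        for i, gid in enumerate(block):
            start = cursor + i * block_spacing
            records.append((f"chr{chrom_idx + 1}", start, start + gene_length, gid))
            placed_on_chrom += 1
        cursor = records[-1][1] + spacing_bp
    for gid in rest:
        next_chrom_if_full()
        records.append((f"chr{chrom_idx + 1}", cursor, cursor + gene_length, gid))
        placed_on_chrom += 1
        cursor += spacing_bp

    import pandas as pd

    ann = pd.DataFrame(records, columns=["chromosome", "start", "end", "gene_id"])
    ann = ann.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    return ann, chosen


def corrupt_reference(
    truth: PlantedGRN, rewire_rate: float, seed: int = 0
) -> Network:
    """Noisy reference network: rewire a fraction of true edges.

    Removes ``rewire_rate`` of the true edges and adds an equal number of
    uniformly random non-edges, preserving the edge count — a stand-in
    for an incomplete, partially wrong interaction database.
    """
    if not (0.0 <= rewire_rate <= 1.0):
        raise ConfigError("rewire_rate must be in [0, 1]")
    rng = _rng(seed, _STAGE_REF)
    edges = sorted(truth.edges)
    m = len(edges)
    n_rewire = int(round(rewire_rate * m))
    drop = set(
        edges[i] for i in rng.choice(m, size=n_rewire, replace=False)
    ) if n_rewire else set()
    kept = [e for e in edges if e not in drop]
    existing = set(edges) | set(kept)
    nodes = list(truth.nodes)
    added: set[Edge] = set()
    while len(added) < n_rewire:
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        e = canonical_edge(nodes[int(i)], nodes[int(j)])
        if e in existing or e in added:
            continue
        added.add(e)
    net = Network(nodes=truth.nodes, B=1)
    for a, b in kept:
        net.add_edge(a, b, weight=1.0)
    for a, b in sorted(added):
        net.add_edge(a, b, weight=1.0)
    return net


@dataclass
class SyntheticBundle:
    """Everything a full pipeline run needs, tied to one global seed."""

    truth: PlantedGRN
    expression: ExpressionMatrix
    genesets_true: GeneSetCollection
    genesets_null: GeneSetCollection
    annotation: object  # pandas DataFrame (chromosome, start, end, gene_id)
    reference_net: Network
    colocated_sets: list[str]
    seed: int


def make_bundle(
    p: int = 500,
    n: int = 180,
    platform: str = "rnaseq",
    exponent: float = 4.0,
    strength_range: tuple[float, float] = (0.2, 0.4),
    k_true: int | None = None,
    k_null: int | None = None,
    size_range: tuple[int, int] | None = None,
    colocate_fraction: float = 0.5,
    spacing_bp: int = 100_000,
    rewire_rate: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate the full synthetic study: truth, data, sets, annotation, reference.

    Defaults emulate the target regime scaled down: a few hundred genes,
    ~180 tumor samples, scale-free truth with exponent 4, moderate
    partial-correlation strengths, and a reference network sharing 70% of
    its edges with the truth.  Planted-set defaults (10 disjoint connected
    sets of 8-15 genes at p=500) scale down with ``p`` so disjoint
    connected growth stays feasible on small simulations.
    """
    if k_true is None:
        k_true = max(1, min(10, p // 50))
    if k_null is None:
        k_null = max(1, min(10, p // 50))
    if size_range is None:
        size_range = (8, 15) if p >= 250 else (5, 8)
    truth = make_planted_grn(
        p, exponent=exponent, seed=seed, strength_range=strength_range
    )
    expression = simulate_expression(
        truth, n, platform=platform, noise_sd=noise_sd, seed=seed
    )
    genesets_true, genesets_null = plant_gene_sets(
        truth, k_true=k_true, k_null=k_null, size_range=size_range, seed=seed
    )
    annotation, colocated = plant_annotation(
        truth,
        genesets_true,
        colocate_fraction=colocate_fraction,
        spacing_bp=spacing_bp,
        seed=seed,
    )
    reference_net = corrupt_reference(truth, rewire_rate=rewire_rate, seed=seed)
    return SyntheticBundle(
        truth=truth,
        expression=expression,
        genesets_true=genesets_true,
        genesets_null=genesets_null,
        annotation=annotation,
        reference_net=reference_net,
        colocated_sets=list(colocated),
        seed=seed,
    )
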