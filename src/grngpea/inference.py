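"""Network inference: MI Pearson estimator, C3Net, BC3Net, relevance networks.

The dependency measure is the Gaussian mutual information derived from the
Pearson correlation coefficient rho,

    I(X, Y) = -1/2 * log(1 - rho^2),

a monotone transform of |rho| that is exact for bivariate normal data.
C3Net keeps, for each gene, only its single strongest statistically
significant MI partner (significance from a permutation null with a
Bonferroni correction), so a p-gene dataset yields at most p edges — the
"core" of the regulatory network.  BC3Net bags C3Net over B bootstrap
resamples of the samples, aggregates edge occurrence counts into ensemble
consensus rates (ECR = count/B) and keeps edges whose counts are
binomially improbable under a self-calibrated background rate.

Two relevance-network baselines are provided: hard percentile thresholds
on |rho| and on CLR-style per-gene z-scores of the MI matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .io_formats import ExpressionMatrix
from .network import Edge, Network, canonical_edge

RHO_SQ_CAP = 1.0 - 1e-12
"""Cap on rho^2: keeps I finite for duplicated genes (|rho| = 1)."""

_NULL_STAGE = 104729  # child-seed tag for the permutation null stream


def _mi_from_rho(rho: np.ndarray | float) -> np.ndarray | float:
    rho_sq = np.clip(np.square(rho), 0.0, RHO_SQ_CAP)
    return -0.5 * np.log1p(-rho_sq)


def mi_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """MI of two sample vectors via the Pearson estimator.

    Requires equal length >= 3 and non-constant vectors; |rho| -> 1 is
    capped at rho^2 = 1 - 1e-12 so the value stays finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("mi_pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise DataError("mi_pearson requires at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    # symmetric in (x, y) by construction, unlike np.corrcoef's off-diagonals
    rho = float(xc @ yc) / math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(_mi_from_rho(rho))


@dataclass
class MIMatrix:
    """All-pairs MI with the underlying correlation matrix.

    Symmetric, non-negative, zero diagonal by convention; I = 0 exactly
    where rho = 0.
    """

    gene_ids: list[str]
    values: np.ndarray = field(repr=False)
    rho: np.ndarray = field(repr=False)


def mi_matrix(m: ExpressionMatrix) -> MIMatrix:
    """All-pairs MI for an expression matrix (constant genes are an error)."""
    if m.n_samples < 3:
        raise DataError("need at least 3 samples")
    if np.any(m.values.std(axis=1) == 0):
        raise DataError("constant gene rows present; run drop_zero_sd_genes first")
    rho = np.corrcoef(m.values)
    rho = (rho + rho.T) / 2.0  # enforce exact symmetry (last-ulp effects)
    mi = np.asarray(_mi_from_rho(rho))
    np.fill_diagonal(mi, 0.0)
    return MIMatrix(gene_ids=list(m.gene_ids), values=mi, rho=rho)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullMIPool:
    """MI magnitudes under the sample-permutation null, sorted ascending."""

    values: np.ndarray = field(repr=False)
    n_draws: int = 0
    seed: int = 0

    def empirical_pvalue(self, mi: np.ndarray | float) -> np.ndarray | float:
        """P(null MI >= mi) with the add-one correction (1+#ge)/(n+1)."""
        n_ge = self.n_draws - np.searchsorted(self.values, mi, side="left")
        return (1.0 + n_ge) / (self.n_draws + 1.0)


def null_mi_pool(
    m: ExpressionMatrix, n_draws: int = 100_000, seed: int = 0
) -> NullMIPool:
    """Sample the null MI distribution by destroying dependence.

    Each draw picks a random gene pair and independently permutes each
    gene's sample order before computing MI; marginals are preserved,
    dependence is not.  Deterministic under ``seed``.
    """
    import logging

    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    if n_draws < 1000:
        logging.getLogger(__name__).warning(
            "null_mi_pool: n_draws=%d is small; the tail will be unstable", n_draws
        )
    rng = np.random.default_rng([seed, _NULL_STAGE])
    p, n = m.values.shape
    sd = m.values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DataError("constant gene rows present; run drop_zero_sd_genes first")
    z = (m.values - m.values.mean(axis=1, keepdims=True)) / sd
    out = np.empty(n_draws)
    chunk = 20_000
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        gi = rng.integers(0, p, size=c)
        gj = rng.integers(0, p - 1, size=c)
        gj = np.where(gj >= gi, gj + 1, gj)  # uniform pair with gi != gj
        perm_i = np.argsort(rng.random((c, n)), axis=1)
        perm_j = np.argsort(rng.random((c, n)), axis=1)
        xi = np.take_along_axis(z[gi], perm_i, axis=1)
        xj = np.take_along_axis(z[gj], perm_j, axis=1)
        rho = np.einsum("ij,ij->i", xi, xj) / n
        out[done : done + c] = _mi_from_rho(rho)
        done += c
    out.sort()
    return NullMIPool(values=out, n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# C3Net
# ---------------------------------------------------------------------------


def _c3net_candidates(mim: MIMatrix) -> dict[Edge, float]:
    """Per-gene maximal-MI partner; ties -> lexicographically smallest id.

    Columns are scanned in gene-id order so ``argmax`` (first maximum)
    realizes the deterministic tie-break.
    """
    p = len(mim.gene_ids)
    order = np.argsort(mim.gene_ids, kind="stable")
    pos_of = np.empty(p, dtype=int)
    pos_of[order] = np.arange(p)
    vals_ord = mim.values[:, order].copy()
    vals_ord[np.arange(p), pos_of] = -np.inf  # exclude self
    best_pos = np.argmax(vals_ord, axis=1)
    best_val = vals_ord[np.arange(p), best_pos]
    best_j = order[best_pos]
    candidates: dict[Edge, float] = {}
    for i in range(p):
        edge = canonical_edge(mim.gene_ids[i], mim.gene_ids[best_j[i]])
        prev = candidates.get(edge)
        if prev is None or best_val[i] > prev:
            candidates[edge] = float(best_val[i])
    return candidates


def c3net(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    pool: NullMIPool | None = None,
    n_null: int = 100_000,
    seed: int = 0,
) -> Network:
    """C3Net: one maximal significant MI partner per gene.

    Each gene nominates its strongest-MI partner as a candidate edge; a
    candidate is kept iff its empirical permutation p-value, Bonferroni
    multiplied by the number of candidate genes, is <= ``alpha``.  The
    union of kept candidates (deduplicated) is the network; edge weight is
    1 and ``B = 1``.
    """
    if pool is None:
        pool = null_mi_pool(m, n_draws=n_null, seed=seed)
    mim = mi_matrix(m)
    candidates = _c3net_candidates(mim)
    n_tests = m.n_genes  # one candidate per gene
    net = Network(nodes=m.gene_ids, B=1)
    for edge, mi in candidates.items():
        p_adj = min(1.0, float(pool.empirical_pvalue(mi)) * n_tests)
        if p_adj <= alpha:
            net.add_edge(edge[0], edge[1], weight=1.0, pvalue_adj=p_adj)
    return net


# ---------------------------------------------------------------------------
# BC3Net
# ---------------------------------------------------------------------------


def bootstrap_indices(seed: int, b: int, n: int) -> np.ndarray:
    """Sample indices (with replacement) for bootstrap replicate ``b``.

    A pure function of (seed, b): results are identical for the same seed
    regardless of evaluation order or parallelism.
    """
    rng = np.random.default_rng([seed, b])
    return rng.integers(0, n, size=n)


def bc3net(
    m: ExpressionMatrix,
    B: int = 100,
    alpha_edge: float = 0.05,
    alpha_c3: float = 0.05,
    seed: int = 0,
    pool: NullMIPool | None = None,
    n_null: int = 100_000,
    resample: bool = True,
) -> Network:
    """Bagged C3Net with binomial edge significance.

    B bootstrap datasets (samples drawn with replacement, size preserved)
    each yield a C3Net network; per-edge occurrence counts k_e over the
    ensemble give the ensemble consensus rate ECR = k_e / B.  Each
    aggregated edge is tested one-sided against Binomial(B, theta0) where
    theta0 = (sum_e k_e) / (B * N), N = p(p-1)/2, i.e. the expected
    per-pair occurrence rate if ensemble edges fell on pairs uniformly;
    Bonferroni factor = number of distinct aggregated edges.  Edges with
    adjusted p <= ``alpha_edge`` are retained.  ``resample=False`` is a
    test hook that feeds the original dataset to every replicate (with
    B=1 this reduces bc3net exactly to c3net).

    The shared permutation null pool is computed once from the original
    matrix and reused across replicates.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    if pool is None:
        pool = null_mi_pool(m, n_draws=n_null, seed=seed)
    counts: dict[Edge, int] = {}
    for b in range(B):
        if resample:
            idx = bootstrap_indices(seed, b, m.n_samples)
            boot = ExpressionMatrix(
                list(m.gene_ids),
                [f"s{i}" for i in range(m.n_samples)],
                m.values[:, idx],
            )
        else:
            boot = m
        # a bootstrap draw can make a gene constant; such genes cannot be
        # scored in this replicate and are dropped from it only
        sd = boot.values.std(axis=1)
        if np.any(sd == 0):
            boot = boot.subset_genes(np.flatnonzero(sd > 0))
        net_b = c3net(boot, alpha=alpha_c3, pool=pool)
        for edge in net_b.edges():
            counts[edge] = counts.get(edge, 0) + 1
    net = Network(nodes=m.gene_ids, B=B)
    if not counts:
        return net
    p = m.n_genes
    n_pairs = p * (p - 1) // 2
    theta0 = sum(counts.values()) / (B * n_pairs)
    n_tests = len(counts)
    for edge, k in counts.items():
        p_raw = float(stats.binom.sf(k - 1, B, theta0))
        p_adj = min(1.0, p_raw * n_tests)
        if p_adj <= alpha_edge:
            net.add_edge(edge[0], edge[1], weight=k / B, pvalue_adj=p_adj)
    return net


# ---------------------------------------------------------------------------
# Relevance-network baselines
# ---------------------------------------------------------------------------


def relevance_network(
    m: ExpressionMatrix, method: str = "abscorr", percentile: float = 0.9
) -> Network:
    """Hard-threshold relevance network.

    ``abscorr`` scores each pair by |rho|; ``clr`` computes per-gene
    z-scores of the MI matrix, z_i(j) = (I_ij - mean_i) / sd_i, and scores
    a pair by sqrt(max(0, z_i)^2 + max(0, z_j)^2).  The network keeps the
    top ``ceil((1 - percentile) * N_pairs)`` pairs by score (ties broken
    by canonical edge order); CLR pairs with zero score are never kept.
    """
    if not (0.0 < percentile < 1.0):
        raise ConfigError("percentile must be in (0, 1)")
    if method not in ("abscorr", "clr"):
        raise ConfigError(f"unknown relevance method {method!r}")
    mim = mi_matrix(m)
    p = len(mim.gene_ids)
    if method == "abscorr":
        score_mat = np.abs(mim.rho.copy())
        np.fill_diagonal(score_mat, 0.0)
    else:
        mi = mim.values.copy()
        np.fill_diagonal(mi, np.nan)
        mean = np.nanmean(mi, axis=1, keepdims=True)
        sd = np.nanstd(mi, axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DataError("degenerate MI matrix: a gene has all-equal MI values")
        z = (mi - mean) / sd
        zp = np.clip(np.nan_to_num(z, nan=0.0), 0.0, None)
        score_mat = np.sqrt(zp**2 + zp.T**2)
    iu, ju = np.triu_indices(p, k=1)
    scores = score_mat[iu, ju]
    if scores.size == 0:
        raise DataError("fewer than 2 genes")
    if np.all(scores == scores[0]):
        raise DataError("degenerate score matrix: all pair scores equal")
    edges = [canonical_edge(mim.gene_ids[i], mim.gene_ids[j]) for i, j in zip(iu, ju)]
    k = int(np.ceil((1.0 - percentile) * scores.size))
    order = sorted(range(scores.size), key=lambda t: (-scores[t], edges[t]))
    net = Network(nodes=m.gene_ids, B=1)
    taken = 0
    for t in order:
        if taken >= k:
            break
        if method == "clr" and scores[t] <= 0:
            break  # zero-score pairs are never selected
        net.add_edge(edges[t][0], edges[t][1], weight=float(scores[t]))
        taken += 1
    return net
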