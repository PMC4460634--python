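# Methods

## Dependency measure and its null

Pairwise dependency between gene expression profiles is the Gaussian
mutual information I(X,Y) = −½·log(1−ρ²), a monotone transform of the
absolute Pearson correlation that is the exact mutual information for
bivariate normal variables. ρ² is capped at 1 − 10⁻¹² so duplicated
genes (|ρ| = 1) map to a large finite value instead of infinity.
Correlations use the standard sample estimator; the (n−1) vs n
denominator cancels in ρ.

Significance of an MI value is judged against a permutation null: each
draw picks a random gene pair and independently permutes each gene's
sample order, destroying dependence while preserving marginals. One pool
of 100,000 draws (configurable) is computed per dataset and shared across
bootstrap replicates — the null depends on the marginals, which
bootstrapping barely changes, and sharing makes the ensemble tractable.
Empirical p-values use the add-one convention p = (1 + #{null ≥ I})/(n_draws + 1),
so the pool's own maximum scores 2/(n_draws+1), never 0.

## C3Net and BC3Net

C3Net nominates, per gene, the partner with maximal MI (ties broken by
lexicographically smallest partner id, so results are platform
independent) and keeps a nominated edge iff its empirical p-value times
the number of nominating genes (Bonferroni) is ≤ α = 0.05. The union of
kept nominations is the network: at most p edges — a deliberately sparse
"core" of the dependency structure.

BC3Net repeats C3Net on B bootstrap datasets (samples resampled with
replacement, size preserved; the index stream is a pure function of
(seed, b), so results do not depend on evaluation order). Edge counts
k_e over the ensemble give the ensemble consensus rate ECR = k_e/B.
Each aggregated edge is tested one-sided against Binomial(B, θ₀).
θ₀ is estimated as (Σ_e k_e)/(B·N) with N = p(p−1)/2 — the expected
per-pair occurrence rate if ensemble edges fell on pairs exchangeably —
which makes the test self-calibrating with no free parameter. The
Bonferroni factor is the number of distinct aggregated edges (the tests
actually performed). A bootstrap draw can render a gene constant; such
genes are dropped from that replicate only, since their correlation is
undefined there.

Relevance-network baselines: `abscorr` scores pairs by |ρ|, `clr` by
sqrt(max(0,z_i)² + max(0,z_j)²) with z per-gene standardized MI values.
Both keep the top ceil((1−percentile)·N) pairs, ties broken by canonical
edge order, so the kept count is exact and deterministic; CLR pairs with
zero score are never kept.

## GPEA

For a network with node universe of size p (the universe is the network
node set, because only those genes can carry edges; sets are intersected
with it and sets left with fewer than two members are untestable and
skipped), N = p(p−1)/2, set pair count m_S = p_S(p_S−1)/2, n network
edges and k within-set edges, the enrichment p-value is the
hypergeometric upper tail P(X ≥ k), computed via scipy's hypergeometric
survival function (verified against exhaustive enumeration to relative
error below 10⁻⁹). k = 0 returns exactly 1. Multiple testing is
Bonferroni by default (adjusted p ≤ α = 0.001 declares significance —
the stringent-α and correction knobs compose and are both exposed) with
BH-FDR available for subnetwork-level comparisons.

The census enrichment is gene-based: for a significant set, the sample
is the genes incident to at least one within-set edge, successes are
census members among the network nodes, and the p-value is the one-sided
hypergeometric tail.

## Gene sets

Genomic co-location sets tile each chromosome with windows of 1 Mb every
500 kb, anchored at coordinate 0; a gene belongs to a window iff its
start coordinate (0-based, half-open intervals; 1-based inputs converted
at the boundary) lies in [w, w + 1 Mb). Start-coordinate assignment is a
single unambiguous rule; windows with fewer than 3 genes are dropped.
`filter_collection` intersects with the universe *before* size filtering
so enrichment counts only testable genes.

## Synthetic data generator

The generator emulates the statistical structure the inference stack
assumes, not any particular tumor biology:

- **Truth network**: degrees drawn from a truncated discrete power law
  P(d) ∝ d^−α on [2, √p], α = 4 by default (matching the degree
  exponents typical of inferred GRNs), realized by a configuration model
  with self-loops/multi-edges removed. Minimum degree 2 is a deliberate
  choice: with minimum degree 1 a power law this steep is subcritical
  (E[d(d−2)] < 0) and has no giant component, while the analysis assumes
  a giant component covering ≥ 90% of genes. Generation retries fresh
  degree sequences until that constraint holds.
- **Expression**: the truth is a Gaussian graphical model — precision
  matrix with −strength (uniform in [0.2, 0.4], positive so marginal
  correlations reinforce rather than cancel) on edges and diagonal = row
  sum of |off-diagonals| + 0.1, guaranteeing positive definiteness with
  a margin away from singularity. Latent profiles are standardized to
  unit variance, then observed as round(exp(0.7·z + 3)) counts followed
  by log1p (RNAseq-like, median count ≈ 20) or as z plus N(0, 0.1²)
  noise (array-like). Under a GGM the planted edges are the strongest
  pairwise dependencies — exactly the C3Net detectability regime. Not
  modelled: library-size and GC artifacts, probe effects, tumor clonal
  heterogeneity; passing tests therefore demonstrate correctness of the
  machinery and detectability under Gaussian dependence, not performance
  on real tumor data.
- **Gene sets**: "true" sets are BFS-grown connected subgraphs of the
  truth, grown disjointly (BFS restricted to unused nodes) so that whole
  sets can later be placed contiguously; null sets are uniform random
  gene samples of matched sizes. Defaults: 10 true + 10 null sets of
  8–15 genes at p = 500, scaled down proportionally for small p so
  disjoint growth stays feasible.
- **Annotation**: half of the true sets (configurable) are laid out
  contiguously, each block aligned to a 500 kb step boundary with
  intra-block spacing compressed so the whole block spans less than one
  window — guaranteeing a single 1 Mb window contains the set. All other
  genes are shuffled and spaced 100 kb apart over 5 chromosomes.
- **Reference network**: the truth with a fraction (default 30%) of
  edges removed and replaced by uniformly random non-edges, preserving
  edge count — an incomplete, partially wrong interaction database.

One global integer seed fans out to per-stage child streams through
fixed stage tags, so each stage is independently reproducible.

## Network statistics

Edge density is n_edges/(n(n−1)/2). The power-law exponent is the exact
discrete MLE at fixed xmin: maximizing −α·Σln d − n·ln ζ(α, xmin)
(Hurwitz zeta) numerically. The often-quoted continuous approximation
α = 1 + n/Σln(d_i/(xmin−½)) is also available (`method="approx"`) but is
strongly biased at small xmin (for a true exponent of 4 at xmin = 1 it
converges to ≈ 2.3), which is why the exact MLE is the default. Shortest
paths are BFS distances (edges are unweighted, so this equals Dijkstra
with unit weights), averaged over all pairs of the giant component; for
graphs above 2000 nodes the mean is estimated from 64 seeded uniformly
sampled source nodes (full BFS each, averaging distances to all
targets — unbiased for the pairwise mean at a fraction of the cost).
Giant-component size ties break by lexicographically smallest member;
hub tables order by degree descending then id ascending.

## Network comparison

The comparison universe defaults to the intersection of the two node
sets (comparing on the union conflates coverage with disagreement; the
union is available for global-table style comparisons). TP/FP/TN/FN
partition the C(u,2) pair space exactly; F = 2PR/(P+R) with F = 0 when
P + R = 0 so distributions are always defined. Per-set comparisons skip
sets whose induced *reference* subgraph has no edges (nothing to agree
with) and report them. The randomized baseline permutes the reference's
node labels uniformly within its node set, per repetition, seeded; an
identity-permutation hook exists for testing. Where a downstream summary
log-transforms F-scores, zeros are offset by 10⁻³.

## Problem sizes and tolerances

Default study conditions: p = 500 genes, n = 180 samples (the regime of
the motivating ~165–190-sample tumor cohorts, scaled to a few hundred
genes), B = 50 bootstraps, 10 replicates; the null-calibration check
uses a fixed 200-node/1990-edge random network with 1000 label-shuffled
40-gene sets, sized so the discrete hypergeometric p-values are fine
grained enough to assess uniformity. Exactness checks (enumeration
oracles, brute-force references) run at N ≤ 12 or p ≤ 8, where
exhaustive computation is feasible.

## Known limitations

- The Pearson-estimator MI sees only monotone (effectively linear)
  dependence; nonlinear regulation invisible to correlation is invisible
  here too.
- θ₀ estimation assumes exchangeability of pairs under the ensemble
  null; strongly modular data could inflate θ₀ and make the binomial
  test conservative.
- The GGM generator produces homoscedastic Gaussian latents; count
  overdispersion beyond the exp/round layer is not modelled.
- Window sets depend on the 0-anchored tiling; a cluster straddling a
  window boundary at an unlucky phase can split across two windows
  (mitigated by the 50% overlap).
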