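# grngpea

Gene regulatory network (GRN) inference and gene-pair enrichment analysis
for tumor expression data, with a fully synthetic benchmark so every stage
is testable without downloads.

## Who this is for

Computational biologists who want to infer an undirected dependency
network from a genes × samples expression matrix (RNAseq log counts or
microarray log intensities), find the functional, gene-family and genomic
regions whose gene pairs are over-wired in that network, characterize the
network's structure, and quantify how well it agrees with a reference
interaction network.

## The methods

**Dependency measure.** Pairwise dependency is the Gaussian mutual
information obtained from the Pearson correlation ρ:

    I(X, Y) = −½ · log(1 − ρ²)

**C3Net / BC3Net.** C3Net keeps, for each gene, only its single
strongest-MI partner whose MI is significant against a permutation null
(sample labels permuted per gene; empirical p with Bonferroni correction,
α = 0.05), giving at most p edges for p genes. BC3Net bags C3Net over
B bootstrap resamples of the samples (default B = 100); the fraction of
bootstrap networks containing an edge is its *ensemble consensus rate*
(ECR), and each aggregated edge is kept if its occurrence count is
improbable under Binomial(B, θ₀) with θ₀ the mean per-pair occurrence
rate, Bonferroni-corrected at α = 0.05. Relevance-network baselines
(hard percentile thresholds on |ρ| and on CLR-style MI z-scores) are
included.

**GPEA.** For p network genes there are N = p(p−1)/2 pairs; a gene set S
with p_S member genes covers m_S = p_S(p_S−1)/2 of them. If the network
has n edges of which k lie within S, the enrichment p-value is the
hypergeometric upper tail

    p(k|S) = Σ_{i=k}^{m_S} C(m_S, i) · C(N−m_S, n−i) / C(N, n),

tested over functional sets (GMT), gene families (GMT) and 1 Mb genomic
windows tiled every 500 kb (co-located gene clusters), with Bonferroni or
BH-FDR control at α = 0.001. A secondary gene-based hypergeometric test
scores each significant subnetwork for enrichment of a census gene list.

**Structure and comparison.** Degree hubs, edge density n/(p(p−1)/2),
giant connected component, discrete power-law exponent (truncated-zeta
MLE), mean BFS path length; and against a reference network: TP/FP/TN/FN,
precision P, recall R, F = 2PR/(P+R), the hypergeometric shared-edge
test, per-subnetwork F-scores, and gene-label-randomized baselines.

**Synthetic benchmark.** A scale-free truth network (configuration model,
degree exponent 4) is realized as a Gaussian graphical model (planted
edges enter the precision matrix); expression is drawn from it with an
RNAseq-count-like or array-noise observation layer; connected subgraphs
are planted as "true" gene sets (with random size-matched nulls), some
laid out contiguously on synthetic chromosomes; and a partially rewired
copy of the truth serves as a noisy reference network.

## Worked example

```bash
python examples/01_simulate_and_infer.py
```

prints

```
planted truth: 300 genes, 382 edges
BC3Net network: 338 edges (ensemble of 50 bootstrap C3Nets)
recovery vs truth: precision=0.976 recall=0.864 F=0.917
```

i.e. from 180 simulated samples BC3Net recovers the planted dependency
skeleton almost exactly: 97.6% of inferred edges are real and 86.4% of
real edges are found. `examples/02_enrichment.py` then shows GPEA ranking
every planted connected set above every random null set (adjusted
p ≤ 6×10⁻⁴ vs p = 1) and flagging exactly the genomic windows where
co-expressed clusters were laid out contiguously;
`examples/03_network_stats.py` and `examples/04_compare_reference.py`
cover structure and reference comparison.

The same stages are scriptable from the shell:

```bash
grn-gpea simulate --genes 300 --samples 180 --seed 7 --outdir out/
grn-gpea infer --expr out/expression.tsv --method bc3net --B 50 --seed 7 --out out/net.tsv
grn-gpea enrich --network out/net.tsv --sets out/genesets_true.gmt --out out/gpea.tsv
grn-gpea pipeline --config config.yaml   # all stages, one manifest
```

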