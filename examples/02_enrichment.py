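"""Gene-pair enrichment analysis (GPEA) on planted and random gene sets.

GPEA asks, per gene set S, whether the network concentrates more edges
among the pairs of S than expected if its n edges fell uniformly on the
N = p(p-1)/2 possible pairs (hypergeometric upper tail).  Planted
connected subgraphs should score tiny p-values; size-matched random
sets should not.
"""

from grngpea import gpea, inference, synthetic
from grngpea.genesets import GeneSetCollection, filter_collection, window_gene_sets

bundle = synthetic.make_bundle(p=300, n=180, seed=7)
net = inference.bc3net(bundle.expression, B=50, seed=7)

merged = GeneSetCollection(
    sets={**bundle.genesets_true.sets, **bundle.genesets_null.sets})
results = gpea.run_gpea(net, merged, alpha=0.001, correction="bonferroni")
print("set        size  edges(k)  p_adj")
for r in results:
    print(f"{r.set_name:10s} {r.p_S:4d}  {r.k:7d}  {r.p_adj:.3g}")
print("-> every planted ('true') set is far more significant than every")
print("   random ('null') set of the same size.\n")

# genomic co-location: 1 Mb windows tiled every 500 kb along chromosomes
wsets = window_gene_sets(bundle.annotation)
wres = gpea.run_gpea(
    net, filter_collection(wsets, min_genes=3, universe=net.node_set))
sig = [r for r in wres if r.p_adj <= 0.001]
print(f"window GPEA: {len(wres)} windows tested, {len(sig)} significant")
for r in sig[:5]:
    print(f"  {r.set_name:25s} k={r.k:3d}  p_adj={r.p_adj:.3g}")
print("-> the significant windows are exactly the regions where planted")
print("   co-expressed clusters were laid out contiguously.")
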