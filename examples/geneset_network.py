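"""Gene-set enrichment, co-occurrence clustering, and directionality.

DEGs are tested for over-representation in each gene set (one-sided
Fisher / hypergeometric tail, BH corrected).  Enriched sets are then
linked by Jaccard similarity on their DEG overlap, clustered into
branches, and each branch is scored for its bias toward downregulated
genes.
"""
import braintx as bt
from braintx import diffexp as de

cfg = bt.StudyConfig(n_genes=3000, n_de_global=200, n_de_regional={}, seed=4)
counts, meta, truth = bt.generate_study(cfg)

down_sets = bt.generate_genesets(truth.universe, 60, (20, 50), 10, truth, seed=4,
                                 down_bias=0.9, name_prefix="DN_")
up_sets = bt.generate_genesets(truth.universe, 8, (20, 50), 8, truth, seed=5,
                               down_bias=0.1, name_prefix="UP_")
sets = bt.GeneSetCollection(sets={**down_sets.sets, **up_sets.sets}, source="synthetic")

res = de.fit_global(de.normalize_log(counts), meta, de.ModelSpec())
deg = sorted(res.index[res["q"] < 0.05])
background = list(res.index)

enr = bt.fisher_enrichment(deg, background, sets.restrict(background), min_overlap=3)
enr = bt.tabulate_direction(enr, sets, res)
sig = enr[enr["q"] < 0.05]
print(f"{len(sig)} / {len(enr)} sets enriched at q < 0.05")
print(sig[["k", "K", "p", "q", "frac_down"]].head(5).round(4).to_string())

J = bt.cooccurrence(bt.GeneSetCollection(sets={s: sets.sets[s] for s in sig.index}),
                    restrict_to=deg)
clusters = bt.cluster_sets(J, k=2)
frac = sig.loc[J.index, "frac_down"]
focal = int(frac.groupby(clusters.labels).mean().idxmax())
stats = bt.directionality_tests(frac, clusters.labels, focal)
print(f"\nfocal cluster {focal}: mean frac_down {stats.focal_mean:.2f} "
      f"vs rest {stats.rest_mean:.2f} (t={stats.t:.2f}, df={stats.df}, p={stats.p:.2g})")
# A positive t means the focal branch is dominated by downregulated
# genes, the signature of a coordinated loss of expression.
edges = bt.network_edges(J, strong_threshold=0.5)
print(f"network: {len(J)} nodes, {len(edges)} edges ({int(edges['strong'].sum())} strong)")
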