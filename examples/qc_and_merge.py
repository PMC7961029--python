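"""Expression QC, region correlation, and cortical merging.

Filters: a gene must reach 1 CPM in at least half the samples of some
region, and its coefficient of variation must stay below mean(CV) + 3 SD.
The two cortical areas are averaged into one "OFC" pseudo-region when
their consensus correlation (median per-subject between-region
correlation of centered expression) is high.
"""
import numpy as np

import braintx as bt
from braintx import preprocess as pp

cfg = bt.StudyConfig(n_genes=4000, n_de_global=100, n_de_regional={}, seed=2)
counts, meta, _ = bt.generate_study(cfg)

cpm = pp.cpm(counts)
expressed = pp.filter_expressed(cpm, meta)
retained = pp.filter_cv(cpm.loc[expressed])
print(f"genes: {len(counts)} -> {len(expressed)} (CPM filter) -> {len(retained)} (CV filter)")

expr = np.log2(cpm.loc[retained] + 1)
for pair in [("BA11", "BA47"), ("BA11", "caudate"), ("caudate", "NAcc")]:
    r = pp.consensus_correlation(expr, meta, *pair)
    print(f"consensus correlation {pair[0]}~{pair[1]}: {r:.2f}")
# The cortical pair is far more correlated than any other pair, which is
# what justifies averaging BA11/BA47 into a single OFC pseudo-region.

merged, meta_m = pp.merge_regions(expr, meta, ["BA11", "BA47"], "OFC")
print(f"after merging: {merged.shape[1]} samples, regions {sorted(meta_m['region'].unique())}")

print("\ncohort demographics (pooled t, df = n1+n2-2):")
print(bt.cohort_table(meta).round(3).to_string())
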