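"""Generate a synthetic case-control brain RNA-seq study with known truth.

The generator emulates a small post-mortem design: 7 case and 8
comparison subjects, four brain regions (two correlated cortical
areas, two striatal), negative-binomial counts, and planted diagnosis
effects concentrated in the striatum.
"""
import braintx as bt

cfg = bt.StudyConfig(n_genes=4000, n_de_global=200, n_de_regional={"caudate": 10, "NAcc": 50}, seed=1)
counts, meta, truth = bt.generate_study(cfg)

print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"subjects: {meta['subject'].nunique()}  regions: {sorted(meta['region'].unique())}")
print("planted DE genes per scope:", {k: len(v) for k, v in truth.de_genes.items()})
print(meta.head(4).to_string())
# Each planted gene carries a +-1 log2 fold change (case minus comparison);
# the truth object is what downstream recovery tests score against.
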