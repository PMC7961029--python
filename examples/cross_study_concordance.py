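"""Cross-study concordance: correlation, BUM mixture, congruent genes.

An external study's DEG table (gene, log2FC, p) is matched to this
study's per-gene results; the two log2FC vectors are correlated; a
beta-uniform mixture fitted to this study's p-values for the matched
genes estimates how much of the external signal replicates; and the
mixture's FDR-0.20 cutoff defines the congruent gene set.
"""
import braintx as bt
from braintx import concordance as cc
from braintx import diffexp as de

cfg = bt.StudyConfig(n_genes=4000, n_de_global=250, n_de_regional={"NAcc": 80}, seed=8)
counts, meta, truth = bt.generate_study(cfg)
partner = bt.generate_partner_study(truth, overlap_frac=0.7, sign_agreement=0.9,
                                    n_report=400, seed=9)

internal = de.fit_regional(de.normalize_log(counts), meta, de.ModelSpec())["NAcc"]
result = bt.match_and_correlate(internal, partner)
print(f"matched genes: {result.n_matched}")
print(f"log2FC correlation r = {result.r:.2f} (p = {result.p_r:.2g})")

fit = bt.fit_bum(result.matched["p_internal"].to_numpy())
print(f"BUM fit: lambda = {fit.lambda_:.3f}, a = {fit.a:.3f}, "
      f"beta fraction = {fit.beta_fraction:.3f}")

tau = bt.fdr_threshold(fit, 0.2)
result = bt.congruent_set(result, tau)
print(f"FDR-0.20 p cutoff tau = {tau:.4f}")
print(f"{result.n_below_tau} genes below tau; {result.n_congruent} congruent in direction")
# A high beta fraction says the partner's DEGs carry signal here too;
# congruent genes replicate with the same direction of effect.
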