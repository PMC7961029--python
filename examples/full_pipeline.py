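"""Run every stage end-to-end from a single config and print the report.

Equivalent shell command:
    braintx run --config config.yaml --outdir out/
"""
import json

import braintx as bt

config = {
    "seed": 1,
    "simulate": {
        "n_genes": 3000,
        "n_de_global": 150,
        "n_de_regional": {"caudate": 10, "NAcc": 40},
        "genesets": {"n_sets": 120, "n_planted": 16},
        "partner": {"n_report": 300},
    },
    "concordance": {"fdr": 0.2},
}

report = bt.run_pipeline(config, "out_full_pipeline")
print("genes passing QC:", report["qc"]["n_after_cv_filter"])
print("cortical consensus:",
      round(report["qc"]["consensus_correlations"]["BA11~BA47"]["median"], 3))
print("DEG counts:", json.dumps(report["de"]["n_deg"], sort_keys=True))
print("enriched sets:", report["enrichment"]["n_enriched"])
print("MSN fraction p:",
      round(report["deconvolution"]["comparison"]["medium_spiny_neuron"]["p"], 4))
print("concordance r:", round(report["concordance"]["r"], 3),
      " congruent:", report["concordance"]["n_congruent"])
# All intermediates (counts, DE tables, enrichment, fractions, report.json)
# are written under out_full_pipeline/ as plain TSV/JSON.
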