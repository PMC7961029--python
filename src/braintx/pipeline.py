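"""End-to-end orchestration: QC -> DE -> enrichment/network -> deconvolution -> concordance.

A single config (dict or YAML) either points at input files or carries a
``simulate`` block; every stage writes its intermediate tables as TSV
under the output directory and contributes to a machine-readable JSON
report.  All randomness flows from the top-level seed through stable
per-stage sub-seeds, so identical config + seed gives byte-identical
reports.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import deconvolution as dc
from . import diffexp as de
from . import enrichment as en
from . import io as bio
from . import network as nw
from . import preprocess as pp
from . import simulate as sim


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, msg: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {msg}")


def stage_seed(seed: int, stage: str) -> int:
    """Stable sub-seed for a named stage (crc32 mix, kept below 2^31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


_STUDY_FIELDS = {f.name for f in dataclasses.fields(sim.StudyConfig)}


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    if has_inputs:
        inputs = config["inputs"]
        for key in ("counts", "metadata"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r}")


def _simulate_inputs(config: dict, outdir: Path) -> dict:
    seed = int(config.get("seed", 0))
    block = dict(config["simulate"])
    genesets_cfg = block.pop("genesets", {})
    mixtures_cfg = block.pop("mixtures", {})
    partner_cfg = block.pop("partner", {})
    study_kwargs = {k: v for k, v in block.items() if k in _STUDY_FIELDS}
    unknown = set(block) - _STUDY_FIELDS
    if unknown:
        raise ValueError(f"unknown simulate key(s): {sorted(unknown)}")
    if "lib_size_range" in study_kwargs:
        study_kwargs["lib_size_range"] = tuple(study_kwargs["lib_size_range"])
    if "regions" in study_kwargs:
        study_kwargs["regions"] = tuple(study_kwargs["regions"])
    if "cortical_regions" in study_kwargs:
        study_kwargs["cortical_regions"] = tuple(study_kwargs["cortical_regions"])
    study = sim.StudyConfig(seed=stage_seed(seed, "study"), **study_kwargs)
    counts, meta, truth = sim.generate_study(study)

    # planted sets split into a down-biased and an up-biased group so the
    # cluster directionality contrast has something to find
    n_planted = int(genesets_cfg.get("n_planted", 15))
    up_frac = float(genesets_cfg.get("up_biased_frac", 0.25))
    n_up = int(round(up_frac * n_planted))
    down_bias = float(genesets_cfg.get("down_bias", 0.8))
    planted_de_frac = float(genesets_cfg.get("planted_de_frac", 0.7))
    size_range = tuple(genesets_cfg.get("set_size_range", (20, 60)))
    collection = sim.generate_genesets(
        universe=truth.universe,
        n_sets=int(genesets_cfg.get("n_sets", 150)) - n_up,
        set_size_range=size_range,
        n_planted=n_planted - n_up,
        truth=truth,
        seed=stage_seed(seed, "genesets"),
        down_bias=down_bias,
        planted_de_frac=planted_de_frac,
        name_prefix="DN_",
    )
    if n_up:
        up_sets = sim.generate_genesets(
            universe=truth.universe,
            n_sets=n_up,
            set_size_range=size_range,
            n_planted=n_up,
            truth=truth,
            seed=stage_seed(seed, "genesets_up"),
            down_bias=1.0 - down_bias,
            planted_de_frac=planted_de_frac,
            name_prefix="UP_",
        )
        collection = en.GeneSetCollection(
            sets={**collection.sets, **up_sets.sets}, source="synthetic"
        )

    reference, _ = sim.generate_reference(seed=stage_seed(seed, "reference"))
    partner = sim.generate_partner_study(
        truth,
        overlap_frac=float(partner_cfg.get("overlap_frac", 0.6)),
        sign_agreement=float(partner_cfg.get("sign_agreement", 0.9)),
        n_report=int(partner_cfg.get("n_report", 300)),
        seed=stage_seed(seed, "partner"),
    )

    bio.write_matrix(counts, outdir / "counts.tsv")
    bio.write_matrix(meta, outdir / "metadata.tsv", index_label="sample")
    en.write_gmt(collection, outdir / "genesets.gmt")
    bio.write_matrix(reference, outdir / "reference.tsv", index_label="cell_type")
    bio.write_matrix(partner, outdir / "partner.tsv", index_label="gene")
    return {
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "genesets": collection,
        "reference": reference,
        "partner": partner,
        "mixtures_cfg": mixtures_cfg,
        "seed": seed,
    }


def _load_inputs(config: dict) -> dict:
    inputs = config["inputs"]
    data = {
        "counts": bio.read_counts(inputs["counts"]),
        "meta": bio.read_metadata(inputs["metadata"]),
        "truth": None,
        "genesets": en.read_gmt(inputs["gmt"]) if "gmt" in inputs else None,
        "reference": pd.read_csv(inputs["reference"], sep="\t", index_col=0)
        if "reference" in inputs
        else None,
        "partner": bio.read_partner_table(inputs["partner"]) if "partner" in inputs else None,
        "mixtures_cfg": {},
        "seed": int(config.get("seed", 0)),
    }
    return data


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": int(config.get("seed", 0))}

    try:
        data = (
            _simulate_inputs(config, outdir) if "simulate" in config else _load_inputs(config)
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", str(e)) from e

    counts, meta = data["counts"], data["meta"]

    # ---- QC ------------------------------------------------------------
    qc_cfg = config.get("qc", {})
    try:
        thresholds = pp.QCThresholds(
            min_cpm=float(qc_cfg.get("min_cpm", 1.0)),
            min_sample_frac=float(qc_cfg.get("min_sample_frac", 0.5)),
            cv_sd_multiplier=float(qc_cfg.get("cv_sd_multiplier", 3.0)),
        )
        cpm_mat = pp.cpm(counts)
        expressed = pp.filter_expressed(cpm_mat, meta, thresholds)
        after_cv = pp.filter_cv(cpm_mat.loc[expressed], thresholds.cv_sd_multiplier)
        counts_qc = counts.loc[after_cv]

        consensus = {}
        regions = sorted(meta["region"].unique())
        for i, ra in enumerate(regions):
            for rb in regions[i + 1 :]:
                try:
                    per_subj = pp.subject_region_correlations(
                        np.log2(cpm_mat.loc[after_cv] + 1.0), meta, ra, rb
                    )
                    consensus[f"{ra}~{rb}"] = {
                        "median": float(per_subj.median()),
                        "mean": float(per_subj.mean()),
                        "n_subjects": int(len(per_subj)),
                    }
                except ValueError:
                    continue

        merge_cfg = {
            "regions": qc_cfg.get("merge_regions", ["BA11", "BA47"]),
            "label": qc_cfg.get("merged_label", "OFC"),
            "threshold": float(qc_cfg.get("merge_threshold", 0.5)),
        }
        merged = False
        expr_log = de.normalize_log(counts_qc)
        mr = merge_cfg["regions"]
        key = f"{min(mr)}~{max(mr)}" if len(mr) == 2 else None
        pair_key = (
            key
            if key in consensus
            else next((k for k in consensus if set(k.split("~")) == set(mr)), None)
        )
        if (
            len(mr) >= 2
            and all(r in regions for r in mr)
            and pair_key is not None
            and consensus[pair_key]["median"] >= merge_cfg["threshold"]
        ):
            expr_log, meta_merged = pp.merge_regions(expr_log, meta, mr, merge_cfg["label"])
            merged = True
        else:
            meta_merged = meta

        cohort = pp.cohort_table(meta)
        bio.write_matrix(expr_log, outdir / "expression_qc.tsv")
        bio.write_matrix(meta_merged, outdir / "metadata_merged.tsv", index_label="sample")
        (outdir / "genes_retained.txt").write_text("\n".join(after_cv) + "\n")
        report["qc"] = {
            "n_genes_input": int(len(counts)),
            "n_after_expression_filter": int(len(expressed)),
            "n_after_cv_filter": int(len(after_cv)),
            "consensus_correlations": consensus,
            "merged_cortical": merged,
            "merged_label": merge_cfg["label"] if merged else None,
            "cohort": {
                cov: {k: round(float(v), 6) for k, v in row.items()}
                for cov, row in cohort.iterrows()
            },
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", str(e)) from e

    # ---- differential expression ---------------------------------------
    de_cfg = config.get("de", {})
    alpha = float(de_cfg.get("alpha", 0.05))
    try:
        spec = de.ModelSpec(
            fixed=tuple(de_cfg.get("fixed", ("diagnosis", "sex", "pH"))),
            candidates=tuple(de_cfg.get("candidates", ("age", "PMI", "RIN"))),
        )
        spec = de.select_model(expr_log, meta_merged, spec)
        res_global = de.fit_global(expr_log, meta_merged, spec, alpha=alpha)
        res_regional = de.fit_regional(expr_log, meta_merged, spec, alpha=alpha)
        all_results = {"global": res_global, **res_regional}
        overlap = de.classify_and_overlap(
            all_results, alpha=alpha, fc_line=float(de_cfg.get("fc_line", 0.26))
        )
        for scope, df in all_results.items():
            bio.write_matrix(df, outdir / f"de_{scope}.tsv")
        report["de"] = {
            "covariates": list(spec.fixed),
            "n_deg": {
                scope: {
                    "total": int((df["q"] < alpha).sum()),
                    "up": int((df["direction"] == "up").sum()),
                    "down": int((df["direction"] == "down").sum()),
                }
                for scope, df in all_results.items()
            },
            "intersections": {
                "&".join(k): v for k, v in overlap["intersections"].items()
            },
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("diffexp", str(e)) from e

    # ---- enrichment + gene-set network ---------------------------------
    enr_cfg = config.get("enrichment", {})
    net_cfg = config.get("network", {})
    try:
        collection = data["genesets"]
        enr_report = {"skipped": True}
        if collection is not None:
            deg_global = sorted(res_global.index[res_global["q"] < alpha])
            background = list(res_global.index)
            enr = en.fisher_enrichment(
                deg_global,
                background,
                collection.restrict(background),
                min_overlap=int(enr_cfg.get("min_overlap", 3)),
            )
            enr = en.tabulate_direction(enr, collection, res_global)
            bio.write_matrix(enr, outdir / "enrichment.tsv", index_label="set")
            enr_alpha = float(enr_cfg.get("alpha", 0.05))
            sig_sets = enr.index[enr["q"] < enr_alpha]
            enr_report = {
                "n_sets_tested": int(len(enr)),
                "n_enriched": int(len(sig_sets)),
                "mean_frac_down_enriched": (
                    float(enr.loc[sig_sets, "frac_down"].mean()) if len(sig_sets) else None
                ),
            }
            if len(sig_sets) >= 4:
                sub = en.GeneSetCollection(
                    sets={s: collection.sets[s] for s in sig_sets}, source=collection.source
                )
                J = nw.cooccurrence(sub, restrict_to=deg_global)
                k = min(int(net_cfg.get("k", 4)), len(J))
                clusters = nw.cluster_sets(J, k=k)
                edges = nw.network_edges(J, float(net_cfg.get("strong_threshold", 0.5)))
                bio.write_matrix(J, outdir / "cooccurrence.tsv", index_label="set")
                clusters.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
                edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
                frac = enr.loc[J.index, "frac_down"]
                means = frac.groupby(clusters.labels).mean()
                sizes = clusters.labels.value_counts()
                eligible = means[sizes[means.index] >= 2]
                if len(eligible) >= 2 and frac.notna().sum() >= 4:
                    focal = int(eligible.idxmax())
                    stats_dir = en.directionality_tests(frac, clusters.labels, focal)
                    enr_report["directionality"] = {
                        "focal_cluster": focal,
                        "focal_mean_frac_down": stats_dir.focal_mean,
                        "rest_mean_frac_down": stats_dir.rest_mean,
                        "t": stats_dir.t,
                        "df": stats_dir.df,
                        "p": stats_dir.p,
                        "anova_F": stats_dir.anova_F,
                        "anova_df": list(stats_dir.anova_df),
                        "anova_p": stats_dir.anova_p,
                        "per_cluster": {
                            str(cidx): {k2: float(v2) for k2, v2 in row.items()}
                            for cidx, row in stats_dir.per_cluster.iterrows()
                        },
                    }
        report["enrichment"] = enr_report
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("enrichment", str(e)) from e

    # ---- deconvolution --------------------------------------------------
    dec_cfg = config.get("deconvolution", {})
    try:
        reference = data["reference"]
        dec_report = {"skipped": True}
        if reference is not None:
            signature = dc.build_signature(reference, n_markers=int(dec_cfg.get("n_markers", 10)))
            if data["truth"] is not None:
                # simulate mode: plant group-shifted fractions and mix them
                mx = data["mixtures_cfg"]
                fractions_true = sim.generate_fractions(
                    meta_merged,
                    cell_types=list(reference.index),
                    shift_type=mx.get("shift_type", "medium_spiny_neuron"),
                    shift=float(mx.get("shift", -0.08)),
                    seed=stage_seed(data["seed"], "fractions"),
                )
                data["truth"].true_fractions = fractions_true
                noise_sd = float(mx.get("noise_sd_frac", 0.05)) * float(
                    signature.to_numpy().mean()
                )
                bulk_mix = sim.generate_mixtures(
                    signature,
                    fractions_true,
                    noise_sd=noise_sd,
                    seed=stage_seed(data["seed"], "mixtures"),
                )
            else:
                bulk_mix = pp.cpm(counts)
            fractions = dc.estimate_fractions(
                bulk_mix, signature, region_map=meta_merged["region"]
            )
            subj_avg = dc.global_average(fractions, meta_merged)
            meta_subj = meta_merged.drop_duplicates("subject").set_index("subject")
            comp = dc.compare_fractions(
                subj_avg,
                meta_subj.loc[subj_avg.index],
                covariates=tuple(dec_cfg.get("covariates", ("sex", "pH"))),
            )
            bio.write_matrix(fractions, outdir / "cell_fractions.tsv", index_label="sample")
            bio.write_matrix(comp, outdir / "fraction_comparison.tsv", index_label="cell_type")
            dec_report = {
                "cell_types": list(fractions.columns),
                "comparison": {
                    ct: {
                        "estimate": None if pd.isna(row["estimate"]) else float(row["estimate"]),
                        "p": None if pd.isna(row["p"]) else float(row["p"]),
                        "q": None if pd.isna(row["q"]) else float(row["q"]),
                    }
                    for ct, row in comp.iterrows()
                },
            }
        report["deconvolution"] = dec_report
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("deconvolution", str(e)) from e

    # ---- concordance -----------------------------------------------------
    con_cfg = config.get("concordance", {})
    try:
        partner = data["partner"]
        con_report = {"skipped": True}
        if partner is not None:
            scope = con_cfg.get("scope")
            if scope is None:
                scope = "NAcc" if "NAcc" in all_results else "global"
            internal = all_results[scope]
            result = cc.match_and_correlate(internal, partner)
            fit = cc.fit_bum(result.matched["p_internal"].to_numpy())
            tau = cc.fdr_threshold(fit, float(con_cfg.get("fdr", 0.2)))
            result = cc.congruent_set(result, tau)
            result.matched.to_csv(outdir / "concordance_matched.tsv", sep="\t")
            con_report = {
                "scope": scope,
                "n_matched": result.n_matched,
                "r": result.r,
                "p_r": result.p_r,
                "lambda": fit.lambda_,
                "a": fit.a,
                "pihat": fit.pihat,
                "signal_fraction": fit.signal_fraction,
                "beta_fraction": fit.beta_fraction,
                "tau": tau,
                "n_below_tau": result.n_below_tau,
                "n_congruent": result.n_congruent,
            }
        report["concordance"] = con_report
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("concordance", str(e)) from e

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
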