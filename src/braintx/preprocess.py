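"""Expression QC, region correlation, cortical merging, cohort statistics.

The QC recipe follows the standard two-stage filter for small bulk
cohorts: a CPM-based expression floor evaluated per brain region, then
removal of genes whose coefficient of variation across all samples is
an outlier (CV above the mean CV plus a multiple of its SD).  Region
similarity is summarized by a per-subject "consensus" correlation used
to decide whether neighbouring cortical areas should be averaged into
one pseudo-region.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class QCThresholds:
    """Expression-filter parameters.

    min_cpm: CPM floor a sample must reach for the gene to count as
        expressed there (default 1).
    min_sample_frac: fraction of a region's samples that must reach the
        floor, with "at least half" realized as ceil at odd n.
    cv_sd_multiplier: k in the CV cutoff T = mean(CV) + k * sd(CV).
    """

    min_cpm: float = 1.0
    min_sample_frac: float = 0.5
    cv_sd_multiplier: float = 3.0


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization; each column sums to 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    return counts * 1e6 / totals


def filter_expressed(
    cpm_matrix: pd.DataFrame, meta: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> list[str]:
    """Genes with CPM >= floor in at least half the samples of some region."""
    retained = np.zeros(len(cpm_matrix), dtype=bool)
    for region, group in meta.groupby("region"):
        cols = [s for s in group.index if s in cpm_matrix.columns]
        if not cols:
            raise ValueError(f"region {region!r} has no samples in the matrix")
        need = math.ceil(thresholds.min_sample_frac * len(cols))
        ok = (cpm_matrix[cols] >= thresholds.min_cpm).sum(axis=1) >= need
        retained |= ok.to_numpy()
    return list(cpm_matrix.index[retained])


def filter_cv(
    expr: pd.DataFrame, cv_sd_multiplier: float = 3.0
) -> list[str]:
    """Drop high-variability genes: keep CV_j < mean(CV) + k * sd(CV).

    Genes with zero mean are excluded before the CV computation (with a
    warning).  In the degenerate case sd(CV) = 0 (all CVs identical, or
    a single gene) the cutoff is treated as +inf and all genes kept.
    """
    if expr.shape[1] < 2:
        raise ValueError("CV filter needs at least 2 samples")
    means = expr.mean(axis=1)
    zero_mean = means <= 0
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} gene(s) with zero mean excluded from CV filter"
        )
    sub = expr.loc[~zero_mean]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    sd_cv = cv.std(ddof=1) if len(cv) > 1 else 0.0
    if not np.isfinite(sd_cv) or sd_cv == 0.0:
        return list(sub.index)
    t_cut = cv.mean() + cv_sd_multiplier * sd_cv
    return list(sub.index[cv < t_cut])


def subject_region_correlations(
    expr: pd.DataFrame, meta: pd.DataFrame, region_a: str, region_b: str
) -> pd.Series:
    """Per-subject Pearson correlation between two regions' profiles.

    Expression is centered per gene within each region first, so the
    statistic captures shared subject-level deviation rather than the
    baseline abundance profile common to all brain samples.
    """
    out = {}
    cols = {}
    for region in (region_a, region_b):
        sub = meta[meta["region"] == region]
        block = expr[[s for s in sub.index if s in expr.columns]]
        cols[region] = (block.sub(block.mean(axis=1), axis=0), sub)
    block_a, meta_a = cols[region_a]
    block_b, meta_b = cols[region_b]
    shared = sorted(set(meta_a["subject"]) & set(meta_b["subject"]))
    for subj in shared:
        sa = meta_a.index[meta_a["subject"] == subj]
        sb = meta_b.index[meta_b["subject"] == subj]
        if len(sa) and len(sb) and sa[0] in block_a and sb[0] in block_b:
            x, y = block_a[sa[0]].to_numpy(), block_b[sb[0]].to_numpy()
            if x.std() > 0 and y.std() > 0:
                out[subj] = float(np.corrcoef(x, y)[0, 1])
    if len(out) < 2:
        raise ValueError(
            f"fewer than 2 subjects shared between {region_a!r} and {region_b!r}"
        )
    return pd.Series(out, name=f"{region_a}~{region_b}")


def consensus_correlation(
    expr: pd.DataFrame, meta: pd.DataFrame, region_a: str, region_b: str
) -> float:
    """Median over subjects of the per-subject between-region correlation."""
    return float(subject_region_correlations(expr, meta, region_a, region_b).median())


def merge_regions(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    regions_to_merge: Iterable[str],
    new_label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average listed regions into one pseudo-sample per subject.

    Samples of the listed regions are replaced by ``subject_newlabel``
    columns holding the per-gene arithmetic mean over that subject's
    samples in those regions; other samples pass through unchanged.
    Subjects absent from all listed regions keep their other samples and
    are skipped with a warning.
    """
    regions_to_merge = list(regions_to_merge)
    in_merge = meta["region"].isin(regions_to_merge)
    keep_meta = meta[~in_merge].copy()
    merged_cols = {}
    merged_rows = []
    for subj, group in meta[in_merge].groupby("subject", sort=False):
        cols = [s for s in group.index if s in expr.columns]
        if not cols:
            warnings.warn(f"subject {subj!r} absent from all merged regions")
            continue
        new_sample = f"{subj}_{new_label}"
        merged_cols[new_sample] = expr[cols].mean(axis=1)
        row = group.iloc[0].copy()
        row["region"] = new_label
        row.name = new_sample
        merged_rows.append(row)
    missing = set(meta["subject"]) - set(meta[in_merge]["subject"])
    for subj in sorted(missing):
        if subj not in set(keep_meta["subject"]):
            warnings.warn(f"subject {subj!r} absent from all merged regions")
    out_expr = pd.concat(
        [expr[[c for c in keep_meta.index if c in expr.columns]], pd.DataFrame(merged_cols)],
        axis=1,
    )
    out_meta = pd.concat([keep_meta, pd.DataFrame(merged_rows)])
    out_meta = out_meta.loc[out_expr.columns]
    return out_expr, out_meta


class PooledT(NamedTuple):
    t: float
    df: int
    p: float


def pooled_two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> PooledT:
    """Two-sample pooled-variance t from group summaries.

    df = n1 + n2 - 2; t is signed (group1 minus group2), two-sided p.
    Computable from summaries alone, so printed demographic tables can
    be checked directly.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = 0.0 if se == 0 else (mean1 - mean2) / se
    p = 1.0 if se == 0 and mean1 == mean2 else float(2 * stats.t.sf(abs(t), df))
    return PooledT(t=t, df=df, p=p)


def cohort_table(
    meta: pd.DataFrame, covariates: Iterable[str] = ("age", "pH", "PMI", "RIN")
) -> pd.DataFrame:
    """Demographic comparison of the diagnosis groups, one subject per row.

    Pooled-variance two-sample t per covariate (df = n1 + n2 - 2); the
    t magnitude is reported, as in demographic tables, with a two-sided p.
    """
    subj = meta.drop_duplicates("subject")
    case = subj[subj["diagnosis"] == "case"]
    comp = subj[subj["diagnosis"] != "case"]
    if len(case) < 2 or len(comp) < 2:
        raise ValueError("each diagnosis group needs at least 2 subjects")
    rows = {}
    for cov in covariates:
        x, y = case[cov].astype(float), comp[cov].astype(float)
        res = pooled_two_sample_t(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        rows[cov] = {
            "case_mean": x.mean(),
            "case_sd": x.std(ddof=1),
            "case_n": len(x),
            "comparison_mean": y.mean(),
            "comparison_sd": y.std(ddof=1),
            "comparison_n": len(y),
            "df": res.df,
            "t": abs(res.t),
            "p": res.p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
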