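"""Cell-type fraction estimation from bulk expression.

Bulk expression of a marker gene is modeled as a convolution of the
cell-type composition and each type's mean expression profile:
``bulk ~ S @ f`` with nonnegative fractions ``f``.  Fractions are
estimated per sample by nonnegative least squares on a marker-gene
signature matrix (linear scale, as additivity requires) and
renormalized to sum to one.  Because medium spiny neurons do not occur
in cortex and excitatory (pyramidal) neurons do not occur in striatum,
each region is solved over its admissible 7-type panel only.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

from .diffexp import bh_fdr

#: cell types excluded from each region class
PANEL_EXCLUSIONS = {
    "cortical": ("medium_spiny_neuron",),
    "striatal": ("excitatory_neuron",),
}

#: default mapping of region labels to panel classes
DEFAULT_REGION_CLASSES = {
    "BA11": "cortical",
    "BA47": "cortical",
    "OFC": "cortical",
    "caudate": "striatal",
    "NAcc": "striatal",
}


def region_class(region: str, classes: dict[str, str] | None = None) -> str | None:
    classes = classes or DEFAULT_REGION_CLASSES
    return classes.get(region)


def build_signature(reference: pd.DataFrame, n_markers: int = 10) -> pd.DataFrame:
    """Select marker genes and assemble the signature matrix.

    ``reference`` is cell-type x gene mean expression (linear scale).
    For each type, genes are ranked by the ratio of that type's mean to
    the maximum mean among the other types; the top ``n_markers`` genes
    with ratio > 1 become its markers.  Returns markers x types.
    """
    if len(reference) < 2:
        raise ValueError("need at least 2 cell types")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference expression must be nonnegative")
    markers: list[str] = []
    for ct in reference.index:
        own = reference.loc[ct]
        others = reference.drop(index=ct).max(axis=0)
        ratio = own / np.maximum(others, 1e-12)
        good = ratio[ratio > 1.0].sort_values(ascending=False)
        if len(good) == 0:
            warnings.warn(f"no marker genes found for cell type {ct!r}")
            continue
        if len(good) < n_markers:
            warnings.warn(
                f"cell type {ct!r}: only {len(good)} marker(s) with positive ratio"
            )
        markers.extend(g for g in good.index[:n_markers] if g not in markers)
    if not markers:
        raise ValueError("no marker genes found for any cell type")
    return reference[markers].T  # markers x types


def estimate_fractions(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    region_map: dict[str, str] | pd.Series,
    region_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample NNLS cell-type fractions over the region's panel.

    ``bulk`` is gene x sample (linear scale); ``region_map`` maps sample
    id to region label.  Each sample is solved over the cell types
    admissible for its region class and renormalized to sum to 1.
    Types outside the panel are NaN in the output, so cortical rows
    carry no medium-spiny-neuron estimate and striatal rows no
    excitatory-neuron estimate.
    """
    region_map = pd.Series(dict(region_map)) if not isinstance(region_map, pd.Series) else region_map
    common = [g for g in signature.index if g in bulk.index]
    if not common:
        raise ValueError("no signature marker genes found in the bulk matrix")
    S_full = signature.loc[common]
    out = pd.DataFrame(np.nan, index=bulk.columns, columns=signature.columns, dtype=float)
    for sample in bulk.columns:
        region = region_map.get(sample)
        rc = region_class(str(region), region_classes) if region is not None else None
        excluded = PANEL_EXCLUSIONS.get(rc, ())
        panel = [t for t in signature.columns if t not in excluded]
        S = S_full[panel].to_numpy()
        if S.shape[0] < S.shape[1]:
            raise ValueError(
                f"sample {sample!r}: fewer markers ({S.shape[0]}) than panel types"
            )
        b = bulk.loc[common, sample].to_numpy(dtype=float)
        if not np.any(b > 0):
            raise ValueError(f"sample {sample!r} has all-zero bulk expression")
        f, _ = nnls(S, b)
        total = f.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r}: degenerate NNLS fit (all-zero)")
        out.loc[sample, panel] = f / total
    return out


def global_average(fractions: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Across-region mean fraction per subject and cell type.

    Types absent from a region (NaN) are skipped, so panel-restricted
    types average over the regions where they exist; a type absent from
    all of a subject's regions stays missing.
    """
    joined = fractions.join(meta[["subject"]])
    return joined.groupby("subject").mean()


def compare_fractions(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    covariates=("sex", "pH"),
) -> pd.DataFrame:
    """Covariate-adjusted diagnosis effect on each cell type's fraction.

    Per type: OLS of fraction on diagnosis (case=1) plus covariates;
    two-sided p on the diagnosis coefficient.  Raw p is the primary
    readout (as in small-cohort composition comparisons); BH q is
    emitted alongside.  A type with constant fractions yields NaN.
    """
    meta = meta.loc[fractions.index]
    if meta["diagnosis"].nunique() < 2:
        raise ValueError("both diagnosis groups must be present")
    rows = {}
    for ct in fractions.columns:
        y = fractions[ct].dropna()
        sub = meta.loc[y.index]
        X = pd.DataFrame({"diagnosis": (sub["diagnosis"] == "case").astype(float)})
        for cov in covariates:
            vals = sub[cov]
            X[cov] = (
                pd.factorize(vals, sort=True)[0].astype(float)
                if vals.dtype == object
                else vals.astype(float)
            )
        if y.nunique() <= 1:
            rows[ct] = {"estimate": np.nan, "se": np.nan, "p": np.nan, "n": len(y)}
            continue
        fit = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        rows[ct] = {
            "estimate": fit.params[1],
            "se": fit.bse[1],
            "p": fit.pvalues[1],
            "n": len(y),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    mask = out["p"].notna()
    out["q"] = np.nan
    out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out
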