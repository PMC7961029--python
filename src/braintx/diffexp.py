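"""Covariate-adjusted differential expression with FDR control.

Per-gene ordinary least squares of log2(CPM + 1) on diagnosis plus
covariates, fitted jointly over all regions (with a region factor) and
per region (without it).  The diagnosis coefficient is the log2 fold
change, case minus comparison, so positive values mean higher
expression in cases.  Fits are vectorized over genes: the hat matrix is
computed once per design and applied to the whole expression matrix,
which is the standard trick for ~10^4 gene-wise linear models.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import cpm


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the per-gene regression.

    ``fixed`` always contains diagnosis; region enters the global model
    only.  ``candidates`` are screened by :func:`select_model` against
    the top expression principal components.
    """

    fixed: tuple[str, ...] = ("diagnosis", "sex", "pH")
    candidates: tuple[str, ...] = ("age", "PMI", "RIN")
    n_pcs: int = 5
    pc_alpha: float = 0.01

    def __post_init__(self):
        if "diagnosis" not in self.fixed:
            raise ValueError("diagnosis must be a fixed covariate")


def normalize_log(counts: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """log2(CPM + prior); the regression response."""
    if prior <= 0:
        raise ValueError("prior must be positive")
    return np.log2(cpm(counts) + prior)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [p, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(meta: pd.DataFrame, covariates, include_region: bool) -> pd.DataFrame:
    """Numeric design matrix with intercept; diagnosis coded case=1."""
    cols = {"intercept": np.ones(len(meta))}
    cols["diagnosis"] = (meta["diagnosis"] == "case").astype(float).to_numpy()
    if include_region:
        regions = sorted(meta["region"].unique())
        for r in regions[1:]:
            cols[f"region[{r}]"] = (meta["region"] == r).astype(float).to_numpy()
    for cov in covariates:
        if cov == "diagnosis":
            continue
        vals = meta[cov]
        if vals.dtype == object or str(vals.dtype) == "category":
            levels = sorted(vals.unique())
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (vals == lv).astype(float).to_numpy()
        else:
            cols[cov] = vals.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.index)


def select_model(expr: pd.DataFrame, meta: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Screen candidate covariates against top expression PCs.

    A candidate is promoted to the fixed set if it correlates with any
    of the top ``n_pcs`` principal components of the (gene-centered)
    expression matrix at p < ``pc_alpha``.  Raises on a (near-)collinear
    pair among the resulting covariates.
    """
    if not spec.candidates:
        return spec
    X = expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0)
    n_pcs = min(spec.n_pcs, min(X.shape) - 1)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]

    selected = []
    for cand in spec.candidates:
        if cand not in meta.columns:
            raise ValueError(f"candidate covariate {cand!r} missing from metadata")
        vals = meta[cand]
        v = (
            pd.factorize(vals, sort=True)[0].astype(float)
            if vals.dtype == object
            else vals.to_numpy(dtype=float)
        )
        for j in range(pcs.shape[1]):
            if np.std(v) == 0:
                break
            _, p = stats.pearsonr(v, pcs[:, j])
            if p < spec.pc_alpha:
                selected.append(cand)
                break

    covs = tuple(spec.fixed) + tuple(selected)
    D = _design(meta, covs, include_region=meta["region"].nunique() > 1)
    Z = D.drop(columns="intercept")
    Zs = (Z - Z.mean()) / Z.std(ddof=0).replace(0, 1.0)
    if Zs.shape[1] >= 2:
        cond = np.linalg.cond(Zs.to_numpy())
        if cond > 1e8:
            corr = Zs.corr().abs()
            for a, b in combinations(corr.columns, 2):
                if corr.loc[a, b] > 0.9999:
                    raise ValueError(f"collinear covariates: {a!r} and {b!r}")
            raise ValueError(f"ill-conditioned design (condition number {cond:.2e})")
    return replace(spec, fixed=covs, candidates=())


def _fit_ols(expr: pd.DataFrame, X: pd.DataFrame, scope: str, alpha: float) -> pd.DataFrame:
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError(f"rank-deficient design for scope {scope!r}")
    if n <= p:
        raise ValueError(
            f"scope {scope!r}: {n} samples cannot identify {p} parameters"
        )
    Y = expr[X.index].to_numpy(dtype=float).T  # samples x genes
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    B = xtx_inv @ Xv.T @ Y  # p x genes
    resid = Y - Xv @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    j = list(X.columns).index("diagnosis")
    beta = B[j]
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pval = 2 * stats.t.sf(np.abs(tstat), dof)
    q = bh_fdr(pval)
    direction = np.where(q < alpha, np.where(beta > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "scope": scope,
            "log2fc": beta,
            "se": se,
            "p": pval,
            "q": q,
            "direction": direction,
        },
        index=expr.index,
    )


def fit_global(
    expr: pd.DataFrame, meta: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> pd.DataFrame:
    """Joint-region DE: log2 expression ~ diagnosis + region + covariates.

    Returns one row per gene with the diagnosis log2FC, its SE, two-sided
    p from the coefficient t-test, BH q over all fitted genes, and a
    direction call at FDR ``alpha``.
    """
    meta = meta.loc[expr.columns]
    for cov in spec.fixed:
        if cov != "diagnosis" and cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
    X = _design(meta, spec.fixed, include_region=meta["region"].nunique() > 1)
    return _fit_ols(expr, X, "global", alpha)


def fit_regional(
    expr: pd.DataFrame, meta: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Per-region DE: same model without the region factor, BH within region."""
    meta = meta.loc[expr.columns]
    out = {}
    for region in sorted(meta["region"].unique()):
        sub = meta[meta["region"] == region]
        X = _design(sub, spec.fixed, include_region=False)
        out[region] = _fit_ols(expr[sub.index], X, region, alpha)
    return out


def classify_and_overlap(
    results: dict[str, pd.DataFrame], alpha: float = 0.05, fc_line: float = 0.26
) -> dict:
    """Volcano classes and DEG-set intersections across analysis scopes.

    Per gene and scope: up/down if q < alpha (sign of log2FC), else ns;
    ``beyond_fc`` annotates |log2FC| > ``fc_line`` (the volcano guide
    line) without affecting significance.  Intersections are computed on
    the significant gene-id sets, both plain (every pair and the full
    triple/k-tuple) and as exclusive Venn regions.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    classes = {}
    sig_sets: dict[str, set] = {}
    for scope, df in results.items():
        cls = df.copy()
        sig = cls["q"] < alpha
        cls["cls"] = np.where(sig, np.where(cls["log2fc"] > 0, "up", "down"), "ns")
        cls["beyond_fc"] = cls["log2fc"].abs() > fc_line
        classes[scope] = cls
        sig_sets[scope] = set(cls.index[sig])

    intersections = {}
    scopes = sorted(sig_sets)
    for r in range(2, len(scopes) + 1):
        for combo in combinations(scopes, r):
            inter = set.intersection(*(sig_sets[s] for s in combo))
            intersections[combo] = len(inter)

    venn_exclusive = {}
    for r in range(1, len(scopes) + 1):
        for combo in combinations(scopes, r):
            inter = set.intersection(*(sig_sets[s] for s in combo))
            for other in set(scopes) - set(combo):
                inter = inter - sig_sets[other]
            venn_exclusive[combo] = len(inter)

    return {
        "classes": classes,
        "sig_sets": sig_sets,
        "intersections": intersections,
        "venn_exclusive": venn_exclusive,
    }
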