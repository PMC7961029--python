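"""Cross-study concordance of differential expression.

Given this study's per-gene results and an external study's table of
nominally significant genes (gene, log2FC, p), the comparison proceeds
in four steps: (1) inner-join on gene id and correlate the two log2FC
vectors; (2) fit a beta-uniform mixture (BUM) to this study's p-values
for the matched genes, f(p) = lambda + (1 - lambda) * a * p^(a-1),
whose fitted upper bound on the null proportion is
pihat = lambda + (1 - lambda) * a; (3) invert the mixture's FDR
expression to get the p cutoff tau attaining a requested FDR; and
(4) count matched genes below tau whose fold-change direction agrees
across studies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

_EPS = 1e-4  # box margin keeping the mixture parameters interior


@dataclass
class BumFit:
    """Maximum-likelihood beta-uniform mixture fit to a p-value vector."""

    lambda_: float
    a: float
    loglik: float
    n: int

    @property
    def pihat(self) -> float:
        """Upper bound on the uniform (null) component weight."""
        return self.lambda_ + (1.0 - self.lambda_) * self.a

    @property
    def signal_fraction(self) -> float:
        """1 - pihat: conservative lower bound on the signal fraction."""
        return 1.0 - self.pihat

    @property
    def beta_fraction(self) -> float:
        """1 - lambda: the fitted weight of the Beta (signal) component."""
        return 1.0 - self.lambda_


@dataclass
class ConcordanceResult:
    n_matched: int
    r: float
    p_r: float
    matched: pd.DataFrame
    n_below_tau: int | None = None
    n_congruent: int | None = None
    congruent_genes: list[str] = field(default_factory=list)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t transform.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 df; usable directly on
    printed (r, n) pairs.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


def match_and_correlate(internal: pd.DataFrame, partner: pd.DataFrame) -> ConcordanceResult:
    """Join the two studies on gene id and correlate log2 fold changes.

    ``internal`` needs columns log2fc and p (gene-indexed); ``partner``
    needs log2FC (gene-indexed).  Pearson r with a two-sided p from the
    t transform on n - 2 df.
    """
    shared = internal.index.intersection(partner.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} matched genes; need >= 3")
    matched = pd.DataFrame(
        {
            "log2fc_internal": internal.loc[shared, "log2fc"],
            "p_internal": internal.loc[shared, "p"],
            "log2fc_partner": partner.loc[shared, "log2FC"],
        }
    )
    r = float(np.corrcoef(matched["log2fc_internal"], matched["log2fc_partner"])[0, 1])
    return ConcordanceResult(
        n_matched=len(shared), r=r, p_r=correlation_pvalue(r, len(shared)), matched=matched
    )


def _bum_nll(theta: np.ndarray, p: np.ndarray) -> float:
    lam, a = theta
    f = lam + (1.0 - lam) * a * p ** (a - 1.0)
    return float(-np.sum(np.log(np.maximum(f, 1e-300))))


# deterministic multi-start grid covering the corners and center of the box
_BUM_STARTS = [(0.5, 0.5), (0.05, 0.1), (0.9, 0.5), (0.5, 0.05), (0.9, 0.9)]


def fit_bum(p, starts=_BUM_STARTS) -> BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture to p-values.

    Bounded L-BFGS-B from several deterministic starts; parameters are
    constrained to (1e-4, 1 - 1e-4).  p-values of exactly 0 are clamped
    to machine epsilon with a warning (the power-law density diverges at
    zero); exact 1s are retained.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 10:
        raise ValueError("need a 1-d vector of at least 10 p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of 0 clamped to machine epsilon")
        p = np.maximum(p, np.finfo(float).eps)

    best = None
    diagnostics = []
    for x0 in starts:
        res = minimize(
            _bum_nll,
            x0=np.array(x0),
            args=(p,),
            method="L-BFGS-B",
            bounds=[(_EPS, 1 - _EPS), (_EPS, 1 - _EPS)],
        )
        diagnostics.append((x0, res.success, float(res.fun)))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"BUM fit failed to converge from all starts: {diagnostics}")
    lam, a = best.x
    return BumFit(lambda_=float(lam), a=float(a), loglik=float(-best.fun), n=len(p))


def bum_fdr_at(fit: BumFit, tau: float) -> float:
    """Estimated FDR of the cutoff ``tau`` under the fitted mixture.

    FDR(tau) = pihat * tau / F(tau) with mixture CDF
    F(tau) = lambda * tau + (1 - lambda) * tau^a.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    F = fit.lambda_ * tau + (1.0 - fit.lambda_) * tau**fit.a
    return fit.pihat * tau / F


def fdr_threshold(fit: BumFit, fdr: float) -> float:
    """p-value cutoff tau at which the mixture's estimated FDR equals ``fdr``.

    Closed-form inversion:
    tau = ((pihat - fdr * lambda) / (fdr * (1 - lambda)))^(1 / (a - 1)),
    clipped to [0, 1]; if pihat - fdr * lambda <= 0 no interior cutoff
    exists and tau = 1.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if not (0 < fit.lambda_ < 1 and 0 < fit.a < 1):
        raise ValueError(f"invalid BUM fit: lambda={fit.lambda_}, a={fit.a}")
    num = fit.pihat - fdr * fit.lambda_
    if num <= 0:
        return 1.0
    ratio = num / (fdr * (1.0 - fit.lambda_))
    tau = ratio ** (1.0 / (fit.a - 1.0))
    return float(np.clip(tau, 0.0, 1.0))


def congruent_set(result: ConcordanceResult, tau: float) -> ConcordanceResult:
    """Count matched genes below tau with matching fold-change direction.

    ``n_below_tau`` counts internal p <= tau; among those,
    ``n_congruent`` counts strict sign agreement of the two log2FCs (a
    zero fold change on either side is non-congruent).
    """
    m = result.matched
    below = m[m["p_internal"] <= tau]
    sign_i = np.sign(below["log2fc_internal"])
    sign_p = np.sign(below["log2fc_partner"])
    congruent = below.index[(sign_i == sign_p) & (sign_i != 0)]
    result.n_below_tau = len(below)
    result.n_congruent = len(congruent)
    result.congruent_genes = list(congruent)
    return result
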