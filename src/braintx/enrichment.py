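"""Fisher-exact gene-set enrichment and directionality statistics.

Over-representation of a DEG list in each gene set is tested with the
one-sided Fisher exact test (equivalently the hypergeometric upper
tail), BH-corrected within a collection.  For each enriched set the
up/down split of its DEG overlap is tabulated; cluster-level
directionality is then summarized by two-sample and one-way-ANOVA
comparisons of the per-set downregulated fraction and per-cluster
one-sample t-tests against 0.5 (Bonferroni corrected), so a
down-biased cluster yields a positive t.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. one MSigDB-style curation)."""

    sets: dict[str, tuple[str, ...]]
    source: str = "user"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, genes) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets emptied by it."""
        genes = set(genes)
        kept = {}
        for name, members in self.sets.items():
            inter = tuple(g for g in members if g in genes)
            if inter:
                kept[name] = inter
            else:
                warnings.warn(f"gene set {name!r} empty after restriction; dropped")
        return GeneSetCollection(sets=kept, source=self.source, descriptions=self.descriptions)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file: tab-separated 'name <tab> description <tab> genes...'."""
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            desc[name] = fields[1]
            sets[name] = tuple(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, source=source or str(path), descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, collection.source)
            fh.write("\t".join([name, desc, *members]) + "\n")


def fisher_enrichment(
    deg,
    background,
    sets: GeneSetCollection,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``deg`` within each gene set.

    The 2x2 table per set is (in set & DE, in set & not DE; not in set &
    DE, rest), tested for over-representation; p equals the
    hypergeometric tail P(X >= k).  Sets overlapping the DEG list by
    fewer than ``min_overlap`` genes are skipped and logged.  BH q is
    computed over the tested sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    deg = set(deg)
    if not deg <= background:
        raise ValueError("DEG list must be a subset of the background")
    N, n = len(background), len(deg)
    rows = []
    for name in sets.sets:
        members = set(sets.sets[name]) & background
        if not members:
            continue
        K = len(members)
        k = len(members & deg)
        if k < min_overlap:
            logger.info("set %s skipped: overlap %d < %d", name, k, min_overlap)
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, K - k, n - k, N - K - n + k
        odds = np.inf if (b == 0 or c == 0) and a * d > 0 else (
            (a * d) / (b * c) if b * c > 0 else np.nan
        )
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "odds_ratio": odds, "p": p})
    result = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["k", "K", "n", "N", "odds_ratio", "p"]
    )
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
    else:
        result["q"] = []
    return result


def tabulate_direction(
    results: pd.DataFrame,
    sets: GeneSetCollection,
    deg_table: pd.DataFrame,
    deg=None,
) -> pd.DataFrame:
    """Fill n_up / n_down / frac_down from each set's DEG overlap.

    ``deg_table`` is a per-gene DE result with a ``direction`` column;
    every overlap gene must appear there with an up/down call.  ``deg``
    defaults to the non-ns genes of ``deg_table``.
    """
    if deg is None:
        deg = set(deg_table.index[deg_table["direction"] != "ns"])
    else:
        deg = set(deg)
    out = results.copy()
    n_up, n_down, frac = [], [], []
    for name in out.index:
        members = set(sets.sets[name])
        overlap = members & deg
        missing = overlap - set(deg_table.index)
        if missing:
            raise ValueError(f"overlap gene(s) missing from DE table: {sorted(missing)[:5]}")
        dirs = deg_table.loc[sorted(overlap), "direction"]
        up, down = int((dirs == "up").sum()), int((dirs == "down").sum())
        n_up.append(up)
        n_down.append(down)
        frac.append(down / (up + down) if up + down else np.nan)
    out["n_up"], out["n_down"], out["frac_down"] = n_up, n_down, frac
    return out


@dataclass
class DirectionalityStats:
    """Cluster-level summaries of the per-set downregulated fraction."""

    focal_cluster: object
    focal_mean: float
    rest_mean: float
    t: float
    df: int
    p: float
    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float
    per_cluster: pd.DataFrame


def directionality_tests(
    frac_down: pd.Series, cluster_labels: pd.Series, focal_cluster
) -> DirectionalityStats:
    """Is the focal cluster more downregulated than the rest?

    Pooled two-sample t of the focal cluster's per-set frac_down against
    all other sets (df = n1 + n2 - 2); one-way ANOVA across clusters
    (df = (k-1, n-k)); and per cluster a one-sample two-sided t of
    frac_down against 0.5 with Bonferroni correction over the tested
    clusters.  Clusters of size 1 are excluded from the per-cluster
    tests with a warning.
    """
    frac_down = frac_down.dropna()
    cluster_labels = cluster_labels.loc[frac_down.index]
    focal = frac_down[cluster_labels == focal_cluster].to_numpy()
    rest = frac_down[cluster_labels != focal_cluster].to_numpy()
    if len(focal) < 2 or len(rest) < 2:
        raise ValueError("need at least 2 sets in the focal cluster and in the rest")
    groups = [frac_down[cluster_labels == c].to_numpy() for c in sorted(cluster_labels.unique())]
    if np.ptp(frac_down.to_numpy()) == 0:
        # degenerate: all fractions identical
        t, p, F, anova_p = 0.0, 1.0, 0.0, 1.0
    else:
        t, p = stats.ttest_ind(focal, rest, equal_var=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, anova_p = stats.f_oneway(*groups)
        if not np.isfinite(F):
            F, anova_p = 0.0, 1.0
    k = len(groups)
    n = len(frac_down)

    tested = [c for c in sorted(cluster_labels.unique()) if (cluster_labels == c).sum() >= 2]
    skipped = sorted(set(cluster_labels.unique()) - set(tested))
    if skipped:
        warnings.warn(f"cluster(s) {skipped} have n=1; excluded from per-cluster tests")
    rows = {}
    for c in tested:
        vals = frac_down[cluster_labels == c].to_numpy()
        if np.std(vals, ddof=1) == 0:
            tc, pc = (0.0, 1.0) if np.isclose(vals.mean(), 0.5) else (np.inf, 0.0)
        else:
            tc, pc = stats.ttest_1samp(vals, 0.5)
        rows[c] = {
            "n": len(vals),
            "mean_frac_down": vals.mean(),
            "t": float(tc),
            "p": float(pc),
            "p_bonf": float(min(1.0, pc * len(tested))),
        }
    return DirectionalityStats(
        focal_cluster=focal_cluster,
        focal_mean=float(focal.mean()),
        rest_mean=float(rest.mean()),
        t=float(t),
        df=len(focal) + len(rest) - 2,
        p=float(p),
        anova_F=float(F),
        anova_df=(k - 1, n - k),
        anova_p=float(anova_p),
        per_cluster=pd.DataFrame.from_dict(rows, orient="index"),
    )
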