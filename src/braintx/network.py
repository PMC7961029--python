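"""Gene-set co-occurrence similarity, clustering, and network edges.

Similarity between two sets is their Jaccard index on the DEG universe
(the fraction of genes shared, out of the unique genes in either set).
Average-linkage hierarchical clustering on distance 1 - J, cut at a
fixed number of branches, replaces the by-eye dendrogram cut; edges
with at least half their genes co-occurring are flagged "strong".
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def cooccurrence(
    sets, restrict_to=None, overlap_coefficient: bool = False
) -> pd.DataFrame:
    """Pairwise Jaccard similarity between gene sets.

    ``restrict_to`` intersects every set with a gene universe (the DEG
    list) first; sets emptied by the restriction are dropped with a
    warning.  With ``overlap_coefficient=True`` the denominator is the
    smaller set size instead of the union.
    """
    collection = sets.restrict(restrict_to) if restrict_to is not None else sets
    names = sorted(collection.sets)
    if len(names) < 2:
        raise ValueError("need at least 2 (non-empty) gene sets")
    genes = sorted(set().union(*(collection.sets[n] for n in names)))
    gidx = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(names), len(genes)), dtype=bool)
    for i, n in enumerate(names):
        for g in collection.sets[n]:
            M[i, gidx[g]] = True
    inter = (M.astype(np.int64) @ M.T.astype(np.int64)).astype(float)
    sizes = M.sum(axis=1).astype(float)
    if overlap_coefficient:
        denom = np.minimum.outer(sizes, sizes)
    else:
        denom = sizes[:, None] + sizes[None, :] - inter
    J = inter / denom
    np.fill_diagonal(J, 1.0)
    return pd.DataFrame(J, index=names, columns=names)


@dataclass
class ClusterAssignment:
    """Flat cut of the gene-set dendrogram."""

    labels: pd.Series  # set name -> cluster id (1..k)
    linkage_matrix: np.ndarray
    k: int


def cluster_sets(J: pd.DataFrame, k: int = 4) -> ClusterAssignment:
    """Average-linkage clustering of sets on distance 1 - J, cut into k."""
    m = len(J)
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}]")
    order = sorted(J.index)
    Js = J.loc[order, order].to_numpy()
    D = 1.0 - Js
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=order, name="cluster"), linkage_matrix=Z, k=k
    )


def network_edges(J: pd.DataFrame, strong_threshold: float = 0.5) -> pd.DataFrame:
    """All positive-similarity pairs; strong iff J >= threshold.

    Self-edges are never emitted.  Columns: source, target, J, strong.
    """
    if not 0.0 <= strong_threshold <= 1.0:
        raise ValueError("strong_threshold must lie in [0, 1]")
    names = list(J.index)
    rows = []
    vals = J.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if vals[i, j] > 0:
                rows.append(
                    {
                        "source": names[i],
                        "target": names[j],
                        "J": float(vals[i, j]),
                        "strong": bool(vals[i, j] >= strong_threshold),
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "J", "strong"])
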