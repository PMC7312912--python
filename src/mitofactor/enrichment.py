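"""Gene-set intersection, hypergeometric over-representation, and heatmap ordering.

Over-representation of a hit list (e.g. the dual-significant genes) in each
set of a collection is scored by the upper-tail hypergeometric probability of
observing at least the overlap by chance, with BH adjustment across sets and
an FDR gate (default 0.05).  The background universe should be the genes
surviving the expression filter, guarding against expression-level bias.

For heatmap-ready output, genes are ordered by complete-linkage agglomerative
clustering under the Pearson correlation distance d(i, j) = 1 − r(i, j) and
rows are mean-centered so color scales split at each gene's mean expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .core_io import ExpressionMatrix, GeneSetCollection
from .factorial import bh_adjust

__all__ = [
    "intersect_expressed",
    "hypergeom_enrich",
    "cluster_order",
    "mean_center",
]


def intersect_expressed(m: ExpressionMatrix, gs: GeneSetCollection, set_name: str) -> set:
    """Members of the named set that are present among the matrix's genes."""
    members = gs[set_name]  # raises KeyError for unknown names
    return set(members) & set(m.gene_ids)


def hypergeom_enrich(hits, gs: GeneSetCollection, fdr: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` in each set.

    For a universe of M genes, a set of n members and N hits, the p-value is
    P(X >= k) for the observed overlap k under the hypergeometric null.
    Returns one row per set with overlap counts, p, BH-adjusted p, and an
    ``enriched`` flag (adjusted_p < fdr), sorted by adjusted p.
    """
    hits = set(hits)
    stray = hits - gs.universe
    if stray:
        raise ValueError(f"hit gene outside universe: {sorted(stray)[0]!r}")
    M = len(gs.universe)
    N = len(hits)
    rows = []
    for name, members in gs.sets.items():
        n = len(members)
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append({"set_name": name, "set_size": n, "overlap": k, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if table.empty:
        table["adjusted_p"] = []
        table["enriched"] = []
        return table
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = table["adjusted_p"] < fdr
    return table.sort_values(["adjusted_p", "p_value", "set_name"]).reset_index(drop=True)


def cluster_order(m: ExpressionMatrix, genes) -> list[str]:
    """Dendrogram leaf order of genes under complete linkage, Pearson distance.

    Distances are d(i, j) = 1 − Pearson correlation of the two genes'
    expression profiles across samples.  Zero-variance genes have no defined
    correlation and raise by name.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"gene not in matrix: {missing[0]!r}")
    keep = [g for g in m.gene_ids if g in set(genes)]
    X = m.values.loc[keep].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = keep[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance gene {bad!r}: Pearson distance undefined")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)  # symmetrize fp noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    order = hierarchy.leaves_list(Z)
    return [keep[i] for i in order]


def mean_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's across-sample mean; output row means are 0."""
    X = m.values.to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(centered, index=m.gene_ids, columns=m.sample_ids), m.scale
    )
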