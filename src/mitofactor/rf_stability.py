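"""Multirun random-forest stability selection of classifier genes.

A single random forest yields a noisy importance ranking; repeating the fit
many times with fresh RNG streams and counting how often each gene lands in
the per-iteration importance top-k gives a stable selection frequency.  The
final classifier list is the frequency-ranked top ``n_select`` genes (ties
broken by mean importance rank, then gene ID), defaulting to a 50-gene list.

Default full-scale configuration is 1000 trees × 1000 iterations; reduced
settings (e.g. 100 × 100) preserve the top set on strongly separable data and
are used for fast runs.  Per-iteration RNG streams are spawned from the
master seed by iteration index, so results do not depend on execution order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core_io import ExpressionMatrix

__all__ = ["multirun_rf", "frequency_report"]


def _resolve_labels(m: ExpressionMatrix, labels) -> np.ndarray:
    if isinstance(labels, (dict, pd.Series)):
        s = pd.Series(labels)
        missing = [x for x in m.sample_ids if x not in s.index]
        if missing:
            raise ValueError(f"no label for sample {missing[0]!r}")
        y = s.loc[m.sample_ids].to_numpy()
    else:
        y = np.asarray(labels)
        if y.shape != (m.n_samples,):
            raise ValueError("labels must have one entry per sample")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    return y


def multirun_rf(
    m: ExpressionMatrix,
    labels,
    n_trees: int = 1000,
    n_iter: int = 1000,
    k_top: int = 50,
    n_select: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated random-forest fits with cross-iteration frequency aggregation.

    Parameters
    ----------
    m : normlog expression matrix (genes × samples).
    labels : two-class sample labels (mapping, Series, or array in sample order).
    n_trees : trees per forest.
    n_iter : number of independent forest fits.
    k_top : per-iteration importance cutoff defining "chosen".
    n_select : size of the final classifier list.
    seed : master seed; per-iteration streams are spawned from it.

    Returns a DataFrame with ``gene_id, selection_frequency,
    mean_importance_rank, selected``, sorted by the selection order.  Exactly
    ``min(n_select, n_genes)`` genes are flagged selected.
    """
    y = _resolve_labels(m, labels)
    n_genes = m.n_genes
    k_top = min(k_top, n_genes)
    X = m.values.to_numpy(dtype=float).T  # samples × genes

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)

    top_counts = np.zeros(n_genes, dtype=np.int64)
    rank_sums = np.zeros(n_genes, dtype=np.float64)
    tiebreak = np.arange(n_genes)
    for child in children:
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=rs, n_jobs=1)
        rf.fit(X, y)
        imp = rf.feature_importances_
        # decreasing importance, ties by original gene order
        order = np.lexsort((tiebreak, -imp))
        ranks = np.empty(n_genes, dtype=np.int64)
        ranks[order] = np.arange(1, n_genes + 1)
        rank_sums += ranks
        top_counts[order[:k_top]] += 1

    freq = top_counts / n_iter
    mean_rank = rank_sums / n_iter
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "selection_frequency": freq,
            "mean_importance_rank": mean_rank,
        }
    )
    table = table.sort_values(
        ["selection_frequency", "mean_importance_rank", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n_sel = min(n_select, n_genes)
    table["selected"] = np.arange(len(table)) < n_sel
    return table


def frequency_report(table: pd.DataFrame) -> pd.DataFrame:
    """Genes sorted by (frequency desc, mean importance rank asc, gene ID asc)."""
    return table.sort_values(
        ["selection_frequency", "mean_importance_rank", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
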