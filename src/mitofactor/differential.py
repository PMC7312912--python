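"""Two-group differential expression with fold-change/p gating and overlap summaries.

The test is a per-gene Welch (unequal-variance) two-sample t test on
normalized natural-log expression, with log2 fold changes obtained by dividing
the natural-log mean difference by ln 2, and BH adjustment across all tested
genes.  It deliberately stands in for a count-model DE engine: the downstream
gating, overlap and direction logic accepts externally computed DE tables, so
a negative-binomial fit (e.g. a DESeq2 run) can be slotted in unchanged.
Output metadata labels the method accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .factorial import bh_adjust

__all__ = [
    "two_group_test",
    "classify_de",
    "venn_overlap",
    "direction_summary",
    "DE_METHOD",
]

LN2 = float(np.log(2.0))

#: method label written to output metadata; not a count-based NB model
DE_METHOD = "welch-t-on-normlog"


def two_group_test(m: ExpressionMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene Welch t test of group B vs group A on normlog expression.

    Returns a table with ``gene_id, log2_fold_change, t, p_value, adjusted_p,
    direction`` where the fold change is mean(B) − mean(A) on the natural-log
    scale divided by ln 2 and direction reflects the default gates of
    :func:`classify_de`.  Degenerate genes with zero variance in both groups
    get p = 1 (no evidence), or p = 0 only never — equal means give p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    for s in group_a + group_b:
        if s not in m.values.columns:
            raise ValueError(f"sample {s!r} not in matrix")
    A = m.values[group_a].to_numpy(dtype=float)
    B = m.values[group_b].to_numpy(dtype=float)
    diff = B.mean(axis=1) - A.mean(axis=1)
    log2fc = diff / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    # zero variance in both groups: identical values -> no evidence (p=1);
    # distinct constants -> infinite t, p=0 handled by scipy as nan too
    degenerate = np.isnan(p)
    p = np.where(degenerate & (np.abs(diff) < 1e-12), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    t = np.where(np.isnan(t), 0.0, t)

    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "log2_fold_change": log2fc,
            "t": t,
            "p_value": p,
            "adjusted_p": bh_adjust(p),
        }
    )
    up, down = classify_de(table)
    table["direction"] = [
        "up" if g in up else ("down" if g in down else "ns") for g in table["gene_id"]
    ]
    table.attrs["method"] = DE_METHOD
    return table


def classify_de(
    table: pd.DataFrame, min_abs_fc: float = 2.0, max_p: float = 0.01, use_adjusted: bool = False
) -> tuple[set, set]:
    """Split a DE table into up/down gene sets with strict threshold comparisons.

    ``min_abs_fc`` is a fold change (not log2): a gene passes only if its
    absolute fold change is strictly greater than ``min_abs_fc`` and its
    p-value strictly below ``max_p``.  ``use_adjusted`` switches the p gate to
    the BH-adjusted column.
    """
    log2_cut = np.log2(min_abs_fc)
    p = table["adjusted_p"] if use_adjusted else table["p_value"]
    fc = table["log2_fold_change"]
    up = set(table.loc[(fc > log2_cut) & (p < max_p), "gene_id"])
    down = set(table.loc[(fc < -log2_cut) & (p < max_p), "gene_id"])
    return up, down


def venn_overlap(set_a, set_b) -> tuple[int, int, int]:
    """Counts (only A, common, only B) of the two-set partition."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def direction_summary(genes, table: pd.DataFrame) -> float:
    """Fraction of ``genes`` with negative log2 fold change in ``table``."""
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    fc = table.set_index("gene_id")["log2_fold_change"]
    missing = genes - set(fc.index)
    if missing:
        raise ValueError(f"gene {sorted(missing)[0]!r} missing from DE table")
    sub = fc.loc[list(genes)]
    return float((sub < 0).sum() / len(genes))
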