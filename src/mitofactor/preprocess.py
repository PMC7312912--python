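"""Normalization chain: quantile normalization, floor + natural log, expression filter.

Order of operations in :func:`normalize_pipeline`: quantile-normalize the FPKM
table across samples, drop genes never exceeding the minimum-expression cutoff
(decided on the FPKM scale), then floor at the threshold and take the natural
log.  The floor precedes the log so that near-zero values cannot blow up the
transformed scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "floor_and_log",
    "filter_expressed",
    "normalize_pipeline",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples to share the same empirical distribution.

    Each sample's k-th order statistic is replaced by the mean of the k-th
    order statistics across samples; tied values within a sample receive the
    mean of the target values their ranks span, so the map is deterministic
    and rank-preserving.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = m.values.to_numpy(dtype=float)
    target = np.sort(X, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # ties: average the target values spanned by each tie group
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), m.scale
    )


def floor_and_log(m: ExpressionMatrix, floor: float = 5.0) -> ExpressionMatrix:
    """Clip values from below at ``floor`` and apply the natural logarithm.

    Returns a ``normlog``-scale matrix.  The default floor of 5 keeps the log
    transform away from the noise-dominated low-expression range.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    X = m.values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("expression values must be nonnegative")
    out = np.log(np.maximum(X, floor))
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids), "normlog"
    )


def filter_expressed(m: ExpressionMatrix, min_fpkm: float = 3.0) -> ExpressionMatrix:
    """Keep genes whose maximum across samples is strictly greater than ``min_fpkm``.

    The filter is defined on the FPKM scale (before the log transform).
    """
    if m.scale != "fpkm":
        raise ValueError(f"expression filter operates on fpkm-scale values, got {m.scale!r}")
    keep = m.values.max(axis=1) > min_fpkm
    return ExpressionMatrix(m.values.loc[keep], m.scale)


def normalize_pipeline(
    m: ExpressionMatrix, floor: float = 5.0, min_fpkm: float = 3.0
) -> ExpressionMatrix:
    """Quantile-normalize → expression filter → floor + natural log."""
    qn = quantile_normalize(m)
    filtered = filter_expressed(qn, min_fpkm=min_fpkm)
    return floor_and_log(filtered, floor=floor)
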