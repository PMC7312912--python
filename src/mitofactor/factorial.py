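"""Per-gene 2×2 factorial regression (genotype × treatment) with orthogonal contrasts.

Each gene's normalized log expression y is modeled by ordinary least squares as

    y = b0 + b_g·G + b_t·T + b_gt·(G·T) + e

with G = +1 for ko / −1 for wt and T = +1 for treated / −1 for untreated.
For a two-level factor the finite orthogonal (Chebyshev) polynomial system
reduces to exactly this ±1 linear contrast, so in a balanced design the model
is the orthogonally coded two-way ANOVA: b_g is half the ko-minus-wt mean
difference and the per-coefficient t test equals the classical 1-df F test
(t² = F).

Per-effect p-values are Benjamini–Hochberg adjusted across genes separately
within each effect family (genotype, treatment, interaction); "dual
significant" genes pass the adjusted-p threshold for both main effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

__all__ = [
    "encode_design",
    "fit_factorial",
    "bh_adjust",
    "select_dual_significant",
    "EFFECTS",
]

EFFECTS = ("genotype", "treatment", "interaction")


def encode_design(design: pd.DataFrame) -> pd.DataFrame:
    """Build the [1, G, T, G·T] design matrix from included samples.

    Returns a DataFrame indexed by sample_id with columns
    ``intercept, genotype, treatment, interaction``.  Both levels of both
    factors must be present among included samples; in a balanced design the
    four columns are mutually orthogonal.
    """
    d = design.loc[design["include"].astype(bool)]
    if d.empty:
        raise ValueError("no included samples in design")
    for factor in ("genotype", "treatment"):
        levels = set(d[factor])
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} has a single level: {sorted(levels)}")
    g = np.where(d["genotype"].to_numpy() == "ko", 1.0, -1.0)
    t = np.where(d["treatment"].to_numpy() == "treated", 1.0, -1.0)
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(d)),
            "genotype": g,
            "treatment": t,
            "interaction": g * t,
        },
        index=pd.Index(d["sample_id"], name="sample_id"),
    )
    return X


def fit_factorial(m: ExpressionMatrix, X: pd.DataFrame) -> pd.DataFrame:
    """OLS fit of the factorial model per gene, with per-effect inference.

    Returns a DataFrame with one row per gene: coefficients (``beta0``,
    ``beta_g``, ``beta_t``, ``beta_gt``), per-effect t statistics, two-sided
    p-values and BH-adjusted p-values (adjusted across genes within each
    effect family), plus the residual degrees of freedom.  With zero residual
    degrees of freedom coefficients are still estimated but t and p are NaN.
    """
    if m.scale != "normlog":
        raise ValueError(f"factorial model expects normlog-scale input, got {m.scale!r}")
    samples = list(X.index)
    missing = [s for s in samples if s not in m.values.columns]
    if missing:
        raise ValueError(f"design sample {missing[0]!r} not in matrix")
    Y = m.values[samples].to_numpy(dtype=float)  # genes × n
    Xa = X.to_numpy(dtype=float)
    n, k = Xa.shape
    if np.linalg.matrix_rank(Xa) < k:
        raise ValueError("design matrix is rank deficient")
    if n < k:
        raise ValueError(f"need at least {k} samples, got {n}")
    df = n - k

    XtX_inv = np.linalg.inv(Xa.T @ Xa)
    B = Y @ Xa @ XtX_inv  # genes × 4
    resid = Y - B @ Xa.T
    rss = np.einsum("ij,ij->i", resid, resid)

    out = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "beta0": B[:, 0],
            "beta_g": B[:, 1],
            "beta_t": B[:, 2],
            "beta_gt": B[:, 3],
            "df": df,
        }
    )
    diag = np.diag(XtX_inv)
    if df >= 1:
        sigma2 = rss / df
        se = np.sqrt(np.outer(sigma2, diag))  # genes × 4
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = B / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        # exact fits (zero residual, zero coefficient) are non-informative
        pvals = np.where(np.isnan(tstat), 1.0, pvals)
    else:
        tstat = np.full_like(B, np.nan)
        pvals = np.full_like(B, np.nan)

    for j, eff in zip((1, 2, 3), EFFECTS):
        out[f"t_{eff}"] = tstat[:, j]
        out[f"p_{eff}"] = pvals[:, j]
        if df >= 1:
            out[f"adj_p_{eff}"] = bh_adjust(pvals[:, j])
        else:
            out[f"adj_p_{eff}"] = np.nan
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_dual_significant(
    table: pd.DataFrame, alpha: float = 0.01, include_interaction: bool = False
) -> set:
    """Genes with BH-adjusted p below ``alpha`` for both main effects.

    With ``include_interaction=True`` the interaction family must also pass
    the threshold.  Comparisons are strict (<).
    """
    mask = (table["adj_p_genotype"] < alpha) & (table["adj_p_treatment"] < alpha)
    if include_interaction:
        mask &= table["adj_p_interaction"] < alpha
    return set(table.loc[mask, "gene_id"])
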