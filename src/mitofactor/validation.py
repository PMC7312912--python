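"""Classifier validation: unsupervised PCA separation and supervised LDA accuracy.

Given a candidate gene list (e.g. the stability-selected classifier genes),
:func:`pca_scores` projects samples onto the principal components of the
gene-restricted, per-gene mean-centered matrix, and :func:`lda_loo_accuracy`
reports leave-one-out cross-validated two-class LDA accuracy.  Because the
gene list is usually larger than the sample count, each LDA training fold is
first projected onto its leading principal components (``min(n_train − 2,
n_genes)`` of them) so the within-class covariance stays well conditioned
without introducing a shrinkage parameter.  Resubstitution accuracy is
available separately for comparison with the optimistic in-sample figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_io import ExpressionMatrix

__all__ = ["pca_scores", "lda_loo_accuracy", "lda_resubstitution_accuracy"]


def _restrict(m: ExpressionMatrix, genes) -> np.ndarray:
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"gene not in matrix: {missing[0]!r}")
    keep = [g for g in m.gene_ids if g in set(genes)]
    return m.values.loc[keep].to_numpy(dtype=float).T  # samples × genes


def _labels_array(m: ExpressionMatrix, labels) -> np.ndarray:
    if isinstance(labels, (dict, pd.Series)):
        s = pd.Series(labels)
        missing = [x for x in m.sample_ids if x not in s.index]
        if missing:
            raise ValueError(f"no label for sample {missing[0]!r}")
        return s.loc[m.sample_ids].to_numpy()
    y = np.asarray(labels)
    if y.shape != (m.n_samples,):
        raise ValueError("labels must have one entry per sample")
    return y


def pca_scores(m: ExpressionMatrix, genes):
    """Project samples onto principal components of the gene-restricted matrix.

    Returns ``(scores, explained_variance)``: a samples × components
    DataFrame and the per-component explained-variance fractions (summing to
    1 over all components).  Per-gene means are removed before the
    decomposition; each component's sign is fixed so its largest-magnitude
    gene loading is positive.
    """
    X = _restrict(m, genes)
    pca = PCA()
    scores = pca.fit_transform(X)  # sklearn centers feature (gene) means
    # fixed sign convention: largest-|loading| positive per component
    for k in range(pca.components_.shape[0]):
        load = pca.components_[k]
        j = np.argmax(np.abs(load))
        if load[j] < 0:
            pca.components_[k] = -load
            scores[:, k] = -scores[:, k]
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def _check_two_classes(y: np.ndarray, min_per_class: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if counts.min() < min_per_class:
        raise ValueError(f"each class needs >= {min_per_class} samples")


def lda_loo_accuracy(m: ExpressionMatrix, genes, labels) -> float:
    """Leave-one-out cross-validated two-class LDA accuracy on a gene set.

    Each fold fits PCA (retaining ``min(n_train − 2, n_genes)`` components)
    on the training samples only, then two-class LDA in that subspace, and
    classifies the held-out sample.  Requires >= 2 samples per class so no
    training fold loses a class entirely.
    """
    X = _restrict(m, genes)
    y = _labels_array(m, labels)
    _check_two_classes(y, min_per_class=2)
    n = X.shape[0]
    correct = 0
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xtr, ytr = X[train], y[train]
        n_comp = max(1, min(len(train) - 2, X.shape[1]))
        pca = PCA(n_components=n_comp)
        Ztr = pca.fit_transform(Xtr)
        lda = LinearDiscriminantAnalysis()
        lda.fit(Ztr, ytr)
        zi = pca.transform(X[i : i + 1])
        correct += int(lda.predict(zi)[0] == y[i])
    return correct / n


def lda_resubstitution_accuracy(m: ExpressionMatrix, genes, labels) -> float:
    """In-sample LDA accuracy (optimistic; reported alongside the LOO figure)."""
    X = _restrict(m, genes)
    y = _labels_array(m, labels)
    _check_two_classes(y, min_per_class=2)
    n_comp = max(1, min(X.shape[0] - 2, X.shape[1]))
    pca = PCA(n_components=n_comp)
    Z = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis()
    lda.fit(Z, y)
    return float((lda.predict(Z) == y).mean())
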