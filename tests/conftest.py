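"""Shared fixtures: tiny hand-built matrices and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mitofactor as mf


def make_matrix(values, gene_ids=None, sample_ids=None, scale="fpkm"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return mf.ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale
    )


@pytest.fixture
def tiny_fpkm():
    return make_matrix([[2.0, 1.0], [4.0, 10.0], [6.0, 100.0]], scale="fpkm")


@pytest.fixture(scope="session")
def planted_two_group():
    """1000-gene two-class dataset with 50 strongly planted genes, normalized.

    25 genes up and 25 down in ko at |log2 effect| = 2 with low biological
    noise (NB size 50); 5 samples per class.  Used by the classifier-selection
    and LDA-validation tests.
    """
    effects = {i: (2.0 if i % 2 == 0 else -2.0) for i in range(50)}
    counts, design, truth = mf.generate_two_group(
        n_genes=1000, n_per_group=5, genotype_effects=effects,
        baseline_mean=200.0, dispersion=50.0, seed=42,
    )
    fpkm = mf.counts_to_fpkm(counts, truth.set_index("gene_id")["length_bp"])
    norm = mf.normalize_pipeline(fpkm, floor=5.0, min_fpkm=3.0)
    labels = design.set_index("sample_id")["genotype"]
    planted = set(truth.loc[truth["log2_genotype_effect"] != 0, "gene_id"])
    return {"norm": norm, "design": design, "labels": labels, "planted": planted}


@pytest.fixture(scope="session")
def rf_selection(planted_two_group):
    """Multirun-RF result on the planted two-group dataset at reduced scale."""
    import time

    d = planted_two_group
    start = time.time()
    table = mf.multirun_rf(
        d["norm"], d["labels"], n_trees=100, n_iter=100, k_top=50, n_select=50, seed=1
    )
    table.attrs["elapsed_s"] = time.time() - start
    return table


@pytest.fixture(scope="session")
def null_welch_pvalues():
    """Welch p-values for one null gene across 250 independent simulations.

    Each replicate simulates a 5-gene, 5-vs-5 two-group dataset with no
    planted effects, floor/log-transforms the FPKM values, and records gene
    0's two-group p-value; under the null these should be uniform on [0, 1].
    """
    pvals = []
    for seed in range(250):
        counts, design, truth = mf.generate_two_group(
            n_genes=5, n_per_group=5, baseline_mean=500.0, dispersion=50.0, seed=seed
        )
        fpkm = mf.counts_to_fpkm(counts, truth.set_index("gene_id")["length_bp"])
        norm = mf.floor_and_log(fpkm)
        groups = design.set_index("sample_id")["genotype"]
        wt = [s for s in norm.sample_ids if groups[s] == "wt"]
        ko = [s for s in norm.sample_ids if groups[s] == "ko"]
        table = mf.two_group_test(norm, wt, ko)
        pvals.append(float(table["p_value"].iloc[0]))
    return np.asarray(pvals)
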