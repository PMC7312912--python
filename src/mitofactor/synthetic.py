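"""Negative-binomial simulator for 2×2 genotype × treatment expression studies.

The generator emulates a bulk RNA-seq experiment on cultured fibroblasts of
two genotypes (``wt`` / ``ko``), half of each treated with a cytokine: counts
for each gene are drawn from a negative binomial whose mean combines a
baseline, multiplicative planted effects, and a per-sample library-size
factor.  Effects are planted on the log2 scale using the same ±1 cell coding
the downstream factorial model fits, so a planted log2 genotype effect of
``e`` is exactly the expected ko-vs-wt log2 fold change and the factorial
genotype coefficient has the closed-form value ``e·ln2/2`` on the natural-log
scale.

A :class:`TruthTable` records, per gene, its mitochondrial label and the three
planted log2 effects (zero means null gene), so every downstream stage has a
ground-truth recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DESIGN_COLUMNS, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "generate",
    "generate_two_group",
    "counts_to_fpkm",
]

LN2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """Parameters of the 2×2 simulation.

    Parameters
    ----------
    n_genes : total number of genes.
    n_per_cell : samples per (genotype × treatment) cell; must be >= 2 so that
        downstream per-group statistics have replication.
    baseline_mean : expected count of a null gene in an average library.
    dispersion : negative-binomial size parameter (mean/size parameterization);
        larger means less biological noise.  Var = mu + mu^2/size.
    genotype_effects, treatment_effects, interaction_effects : maps from gene
        index to planted log2 effect size.
    frac_mito : fraction of genes labeled mitochondrial in the truth table.
    gene_lengths_bp : per-gene transcript lengths; drawn uniformly in
        [500, 5000) when omitted.
    libsize_factors : per-sample relative sequencing-depth multipliers; drawn
        log-normal (sigma 0.15) when omitted, emulating modest depth variation.
    add_low_quality_sample : append one extra ko/treated sample with a
        severely reduced library (factor 0.05) flagged include=False, to
        exercise the declarative sample-exclusion path.
    seed : RNG seed; identical configs with identical seeds reproduce output
        bit-identically.
    """

    n_genes: int = 1000
    n_per_cell: int = 4
    baseline_mean: float = 200.0
    dispersion: float = 10.0
    genotype_effects: dict[int, float] = field(default_factory=dict)
    treatment_effects: dict[int, float] = field(default_factory=dict)
    interaction_effects: dict[int, float] = field(default_factory=dict)
    frac_mito: float = 0.1
    gene_lengths_bp: np.ndarray | None = None
    libsize_factors: np.ndarray | None = None
    add_low_quality_sample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2 (downstream tests need replication)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not 0.0 <= self.frac_mito <= 1.0:
            raise ValueError("frac_mito must be in [0, 1]")
        for table in (self.genotype_effects, self.treatment_effects, self.interaction_effects):
            for idx, eff in table.items():
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"planted gene index {idx} out of range")
                if not np.isfinite(eff):
                    raise ValueError(f"effect size for gene {idx} is not finite")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _effect_matrix(cfg: SimulationConfig, g_code: np.ndarray, t_code: np.ndarray) -> np.ndarray:
    """log2 multiplier per gene × sample under the ±1 cell coding."""
    n = cfg.n_genes
    eff_g = np.zeros(n)
    eff_t = np.zeros(n)
    eff_gt = np.zeros(n)
    for i, e in cfg.genotype_effects.items():
        eff_g[i] = e
    for i, e in cfg.treatment_effects.items():
        eff_t[i] = e
    for i, e in cfg.interaction_effects.items():
        eff_gt[i] = e
    # half-effect per ±1 code so the ko-vs-wt (or treated-vs-untreated)
    # contrast equals the planted log2 effect
    return (
        0.5 * np.outer(eff_g, g_code)
        + 0.5 * np.outer(eff_t, t_code)
        + 0.5 * np.outer(eff_gt, g_code * t_code)
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    # numpy parameterizes NB by (n, p) with mean n(1-p)/p; mean/size gives
    # p = size / (size + mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate(cfg: SimulationConfig):
    """Simulate counts, design and truth for the full 2×2 layout.

    Returns ``(counts, design, truth)`` where ``counts`` is a count-scale
    :class:`~mitofactor.core_io.ExpressionMatrix`, ``design`` a sample design
    DataFrame enumerating the four cells, and ``truth`` a per-gene table of
    mitochondrial labels and planted log2 effects.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    cells = [("wt", "untreated"), ("wt", "treated"), ("ko", "untreated"), ("ko", "treated")]
    sample_ids, genotypes, treatments = [], [], []
    for geno, treat in cells:
        for r in range(1, cfg.n_per_cell + 1):
            sample_ids.append(f"{geno}_{treat}_{r}")
            genotypes.append(geno)
            treatments.append(treat)
    include = [True] * len(sample_ids)
    if cfg.add_low_quality_sample:
        sample_ids.append("ko_treated_lowqc")
        genotypes.append("ko")
        treatments.append("treated")
        include.append(False)
    n_samples = len(sample_ids)

    g_code = np.where(np.array(genotypes) == "ko", 1.0, -1.0)
    t_code = np.where(np.array(treatments) == "treated", 1.0, -1.0)

    if cfg.gene_lengths_bp is not None:
        lengths = np.asarray(cfg.gene_lengths_bp, dtype=float)
        if lengths.shape != (cfg.n_genes,) or (lengths <= 0).any():
            raise ValueError("gene_lengths_bp must be positive with one entry per gene")
    else:
        lengths = rng.integers(500, 5000, size=cfg.n_genes).astype(float)

    if cfg.libsize_factors is not None:
        libfac = np.asarray(cfg.libsize_factors, dtype=float)
        if libfac.shape != (n_samples,) or (libfac <= 0).any():
            raise ValueError("libsize_factors must be positive with one entry per sample")
    else:
        libfac = np.exp(rng.normal(0.0, 0.15, size=n_samples))
        if cfg.add_low_quality_sample:
            libfac[-1] = 0.05

    log2_eff = _effect_matrix(cfg, g_code, t_code)
    mean = cfg.baseline_mean * np.power(2.0, log2_eff) * libfac[None, :]
    counts = _nb_draw(rng, mean, cfg.dispersion)

    values = pd.DataFrame(counts, index=genes, columns=sample_ids, dtype=float)
    matrix = ExpressionMatrix(values, "count")

    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "genotype": genotypes,
            "treatment": treatments,
            "include": include,
        }
    )[DESIGN_COLUMNS]

    n_mito = int(round(cfg.frac_mito * cfg.n_genes))
    mito_idx = set(rng.choice(cfg.n_genes, size=n_mito, replace=False).tolist())
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_mito": [i in mito_idx for i in range(cfg.n_genes)],
            "log2_genotype_effect": [cfg.genotype_effects.get(i, 0.0) for i in range(cfg.n_genes)],
            "log2_treatment_effect": [cfg.treatment_effects.get(i, 0.0) for i in range(cfg.n_genes)],
            "log2_interaction_effect": [
                cfg.interaction_effects.get(i, 0.0) for i in range(cfg.n_genes)
            ],
            "length_bp": lengths.astype(int),
        }
    )
    return matrix, design, truth


def generate_two_group(
    n_genes: int,
    n_per_group: int,
    genotype_effects: dict[int, float] | None = None,
    baseline_mean: float = 200.0,
    dispersion: float = 10.0,
    frac_mito: float = 0.1,
    seed: int = 0,
):
    """Simulate a plain two-class (wt vs ko, all untreated) dataset.

    Convenience wrapper around the same NB machinery for classifier
    experiments where treatment plays no role.  Returns
    ``(counts, design, truth)`` like :func:`generate`.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    sample_ids = [f"wt_{r}" for r in range(1, n_per_group + 1)] + [
        f"ko_{r}" for r in range(1, n_per_group + 1)
    ]
    genotypes = ["wt"] * n_per_group + ["ko"] * n_per_group
    g_code = np.where(np.array(genotypes) == "ko", 1.0, -1.0)

    cfg = SimulationConfig(
        n_genes=n_genes,
        n_per_cell=2,  # unused beyond validation
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        genotype_effects=dict(genotype_effects or {}),
        frac_mito=frac_mito,
        seed=seed,
    )
    lengths = rng.integers(500, 5000, size=n_genes).astype(float)
    libfac = np.exp(rng.normal(0.0, 0.15, size=len(sample_ids)))

    log2_eff = _effect_matrix(cfg, g_code, np.zeros_like(g_code))
    mean = baseline_mean * np.power(2.0, log2_eff) * libfac[None, :]
    counts = _nb_draw(rng, mean, dispersion)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids, dtype=float), "count"
    )
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "genotype": genotypes,
            "treatment": ["untreated"] * len(sample_ids),
            "include": [True] * len(sample_ids),
        }
    )[DESIGN_COLUMNS]
    n_mito = int(round(frac_mito * n_genes))
    mito_idx = set(rng.choice(n_genes, size=n_mito, replace=False).tolist())
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_mito": [i in mito_idx for i in range(n_genes)],
            "log2_genotype_effect": [
                (genotype_effects or {}).get(i, 0.0) for i in range(n_genes)
            ],
            "log2_treatment_effect": 0.0,
            "log2_interaction_effect": 0.0,
            "length_bp": lengths.astype(int),
        }
    )
    return matrix, design, truth


def counts_to_fpkm(counts: ExpressionMatrix, lengths_bp, libsizes=None) -> ExpressionMatrix:
    """Convert raw counts to FPKM: ``count × 10^9 / (length_bp × libsize)``.

    ``lengths_bp`` maps gene → transcript length in bp (array in matrix gene
    order, or a mapping/Series).  ``libsizes`` are per-sample total mapped
    fragments; they default to the matrix column sums.
    """
    if counts.scale != "count":
        raise ValueError(f"expected a count-scale matrix, got scale={counts.scale!r}")
    if isinstance(lengths_bp, (pd.Series, dict)):
        lengths = pd.Series(lengths_bp).reindex(counts.gene_ids)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"no length for gene {missing!r}")
        lengths = lengths.to_numpy(dtype=float)
    else:
        lengths = np.asarray(lengths_bp, dtype=float)
        if lengths.shape != (counts.n_genes,):
            raise ValueError("lengths_bp must have one entry per gene")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")

    if libsizes is None:
        libsizes = counts.values.sum(axis=0).to_numpy(dtype=float)
    else:
        if isinstance(libsizes, (pd.Series, dict)):
            libsizes = pd.Series(libsizes).reindex(counts.sample_ids).to_numpy(dtype=float)
        else:
            libsizes = np.asarray(libsizes, dtype=float)
        if libsizes.shape != (counts.n_samples,):
            raise ValueError("libsizes must have one entry per sample")
    if (libsizes <= 0).any() or np.isnan(libsizes).any():
        raise ValueError("library sizes must be positive")

    fpkm = counts.values.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libsizes[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids), "fpkm"
    )
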