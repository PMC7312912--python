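"""Core containers and file I/O for expression matrices, sample designs and gene sets.

The pipeline works on three kinds of objects:

* :class:`ExpressionMatrix` — a genes × samples grid of nonnegative expression
  values carrying an explicit scale tag (``count``, ``fpkm`` or ``normlog``),
  so that downstream stages can refuse input on the wrong scale.
* a *sample design* table — one row per sample with its genotype (``wt``/``ko``),
  treatment (``untreated``/``treated``) and an ``include`` flag used for
  declarative sample exclusion (e.g. dropping a low-quality library).
* :class:`GeneSetCollection` — named gene-ID sets over an explicit universe,
  read from standard GMT files (MitoCarta-style localization sets, pathways).

All tabular files are plain TSV; gene/sample identifiers are matched as exact
strings (no case folding, no cross-species symbol mapping).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCALES",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "apply_design",
    "read_gmt",
    "write_gmt",
    "load_config",
]

SCALES = ("count", "fpkm", "normlog")

GENOTYPES = ("wt", "ko")
TREATMENTS = ("untreated", "treated")

DESIGN_COLUMNS = ["sample_id", "genotype", "treatment", "include"]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a scale tag.

    ``values`` is a DataFrame indexed by gene ID with sample IDs as columns.
    Invariants (checked on construction): unique gene and sample IDs, finite
    nonnegative entries, and integer-valued entries when ``scale == "count"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale in ("count", "fpkm") and arr.size and (arr < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.scale == "count" and arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("count-scale matrix must be integer-valued")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in matrix order); missing genes raise."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"gene not in matrix: {missing[0]!r}")
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"sample not in matrix: {missing[0]!r}")
        return ExpressionMatrix(self.values[samples], self.scale)


@dataclass
class GeneSetCollection:
    """Named gene-ID sets over an explicit universe.

    Every member of every set must belong to the universe; set names are
    unique by construction (dict keys).
    """

    sets: dict[str, frozenset]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        else:
            self.universe = frozenset(self.universe)
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    def __getitem__(self, name: str) -> frozenset:
        if name not in self.sets:
            raise KeyError(f"unknown gene set: {name!r}")
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_matrix(path, scale: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample IDs, first column = gene IDs)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and any(f.strip() for f in r)]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    header = rows[0]
    sample_ids = [h.strip() for h in header[1:]]
    if len(rows) == 1:
        raise ValueError(f"{path}: no data rows")
    gene_ids = []
    data = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        gene_ids.append(row[0].strip())
        try:
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    seen: set = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"{path}: duplicate gene ID: {g!r}")
        seen.add(g)
    values = pd.DataFrame(data, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values, scale)


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; round-trips through :func:`read_matrix`."""
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV with columns sample_id, genotype, treatment, include."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    df = df[DESIGN_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in design: {dup!r}")
    bad_g = set(df["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValueError(f"unknown genotype level(s): {sorted(bad_g)}")
    bad_t = set(df["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise ValueError(f"unknown treatment level(s): {sorted(bad_t)}")
    if df["include"].dtype != bool:
        df["include"] = (
            df["include"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df["include"].isna().any():
            raise ValueError("include column must be boolean (true/false/1/0)")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def apply_design(m: ExpressionMatrix, design: pd.DataFrame) -> ExpressionMatrix:
    """Restrict a matrix to the design's ``include=True`` samples.

    Column order of the retained samples is preserved. Every matrix sample
    must appear in the design; missing samples raise by name.
    """
    design_ids = set(design["sample_id"])
    for s in m.sample_ids:
        if s not in design_ids:
            raise ValueError(f"sample {s!r} missing from design table")
    included = set(design.loc[design["include"].astype(bool), "sample_id"])
    keep = [s for s in m.sample_ids if s in included]
    if not keep:
        raise ValueError("no samples remain after applying design exclusions")
    return ExpressionMatrix(m.values[keep], m.scale)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file: one set per line as ``name <TAB> description <TAB> members...``.

    The universe defaults to the union of all members; pass ``universe`` to
    override (e.g. with the post-filter expressed genes), in which case set
    members outside the given universe are dropped, as in standard
    over-representation backgrounds.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields (name, description, members)"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}: duplicate set name: {name!r}")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets[name] = members
    if universe is not None:
        uni = frozenset(universe)
        sets = {name: members & uni for name, members in sets.items()}
        return GeneSetCollection(sets, uni)
    union = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, union)


def write_gmt(gs: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in gs.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def load_config(path) -> Mapping:
    """Load a YAML run-configuration file (flat mapping of stage parameters)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg
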