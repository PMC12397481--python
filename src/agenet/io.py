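"""Validated containers and TSV/GCT readers for expression data.

Every downstream stage consumes only the types defined here, so malformed
input (duplicate ids, NaNs, ragged rows, negative values) is rejected at
the boundary and never propagates.

Expression matrices are genes x samples. Two dialects are read and written:
plain TSV (first column gene id, header row of sample ids) and GCT 1.2
(the same table preceded by a ``#1.2`` line and an ``n_genes\tn_samples``
dimension line; a GCT ``Description`` column is tolerated and dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("agenet")

YOUNG = "young"
AGING = "aging"
GROUPS = (YOUNG, AGING)


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis thresholds and classifier settings for one pipeline run.

    Defaults encode the published analysis choices: genes enter a
    co-expression network when median TPM > 5 in that condition, edges are
    kept at BH FDR < 0.05, DEGs at adjusted p < 0.05, the top 10% of nodes
    by absolute degree change are dysregulated, a gene is shared by "Many"
    tissues from 14 up, tissues need more than 10 samples per group, and
    the random forest uses 1000 trees on a stratified 70/30 split.
    """

    tpm_filter_threshold: float = 5.0
    edge_fdr: float = 0.05
    de_adj_p: float = 0.05
    dn_fraction: float = 0.10
    many_min_tissues: int = 14
    some_min_tissues: int = 2
    min_samples_per_group: int = 10
    filter_rule: str = "median"  # median | mean | all
    edge_p_method: str = "permutation"  # permutation | t
    normalize_degree: bool = False
    batch_center: bool = False
    rf_trees: int = 1000
    rf_train_fraction: float = 0.70
    rf_top_k: int = 40
    rf_zscore_composite: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_fdr", "de_adj_p", "dn_fraction", "rf_train_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (name == "dn_fraction" and v == 1.0):
                raise ValidationError(f"{name} must be in (0, 1): got {v!r}")
        for name in ("many_min_tissues", "some_min_tissues", "min_samples_per_group",
                     "rf_trees", "rf_top_k"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"{name} must be an integer >= 1: got {v!r}")
        if self.some_min_tissues >= self.many_min_tissues:
            raise ValidationError("some_min_tissues must be < many_min_tissues")
        if self.filter_rule not in ("median", "mean", "all"):
            raise ValidationError(f"unknown filter_rule {self.filter_rule!r}")
        if self.edge_p_method not in ("permutation", "t"):
            raise ValidationError(f"unknown edge_p_method {self.edge_p_method!r}")
        if self.tpm_filter_threshold < 0:
            raise ValidationError("tpm_filter_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a unit tag (``tpm`` or ``counts``).

    ``data`` index = gene ids, columns = sample ids; values finite, >= 0;
    counts must be (numerically) integral.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "counts"):
            raise ValidationError(f"unit must be 'tpm' or 'counts', got {self.unit!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}")
        if self.unit == "counts" and not np.allclose(values, np.round(values)):
            raise ValidationError("counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.unit)


def read_expression(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a plain-TSV or GCT 1.2 expression table.

    The dialect is sniffed from the first line (``#1.2`` => GCT). Duplicate
    gene/sample ids, non-numeric cells and ragged rows raise
    :class:`ValidationError` naming the offending row or column.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
    skiprows = 2 if first.startswith("#1.2") else 0
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValidationError(f"{path}: malformed table: {exc}") from exc
    # GCT 1.2 has a Description column after the id column
    if skiprows and len(df.columns) and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric cell in column {col!r}"
                f" (first bad row: {bad.index[0]!r})" if len(bad) else
                f"{path}: non-numeric column {col!r}")
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing values (ragged rows?)")
    return ExpressionMatrix(df, unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     gct: bool = False) -> None:
    """Write a matrix as TSV, optionally with the 2-line GCT 1.2 preamble."""
    path = Path(path)
    with path.open("w") as fh:
        if gct:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.data.copy()
        out.index.name = "gene_id"
        if gct:
            out.insert(0, "Description", out.index)
            out.index.name = "Name"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample table: sample_id, group (young|aging), tissue, batch.

    Group is strictly binary — a middle age band never enters the pipeline.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "group", "tissue", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = self.table.reset_index(drop=True).astype(
            {c: str for c in self.REQUIRED})
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"group must be one of {GROUPS}, got {bad}")
        object.__setattr__(self, "table", t)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def for_tissue(self, tissue: str) -> "SampleMetadata":
        return SampleMetadata(self.table[self.table["tissue"] == tissue])

    def samples_in_group(self, group: str, tissue: str | None = None) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t.loc[t["group"] == group, "sample_id"])

    def group_sizes(self, tissue: str) -> dict[str, int]:
        return {g: len(self.samples_in_group(g, tissue)) for g in GROUPS}


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def check_group_sizes(meta: SampleMetadata, config: RunConfig) -> dict[str, bool]:
    """Per-tissue pass/fail of the minimum-group-size rule.

    A tissue passes iff BOTH groups have strictly more than
    ``config.min_samples_per_group`` samples ("more than 10" is taken
    literally: 10/10 fails, 11/11 passes).
    """
    result: dict[str, bool] = {}
    for tissue in meta.tissues():
        sizes = meta.group_sizes(tissue)
        ok = all(sizes[g] > config.min_samples_per_group for g in GROUPS)
        result[tissue] = ok
        if not ok:
            logger.warning("tissue %s fails group-size check: %s", tissue, sizes)
    return result


def strip_ensembl_version(gene_ids: list[str]) -> list[str]:
    """Optional id normalization: drop a trailing '.N' Ensembl version."""
    return [g.rsplit(".", 1)[0] if "." in g and g.rsplit(".", 1)[1].isdigit()
            else g for g in gene_ids]
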