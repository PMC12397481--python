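"""Per-tissue two-group differential expression.

The built-in test is a Welch two-sample t-test on log2(TPM + 1) between
the aging and young groups, with Benjamini-Hochberg adjustment across all
tested genes of the tissue. ``log2fc`` is aging minus young on that scale.
A gene is significant iff its adjusted p is below the configured
threshold; direction is the sign of log2fc with no magnitude cutoff.

Because TPM is compositional, a strong expression change in a subset of
genes deflates every other gene's TPM and would masquerade as widespread
opposite-direction change. ``builtin_de`` therefore applies a
median-of-ratios sample normalization (the same idea count-based DE
engines use for size factors) before testing: each sample's log2(TPM+1)
column is shifted by the median, over genes, of its deviation from the
gene-wise mean profile. Under a balanced null this shift is ~0; under
asymmetric planted change it removes the compositional offset, because
the median gene is unchanged.

Results computed externally with a count-based NB-GLM engine can be
ingested via :func:`ingest_external_de`; the same significance and
direction rules are applied on top, so downstream stages are agnostic to
which engine produced the table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (AGING, YOUNG, ExpressionMatrix, RunConfig, SampleMetadata,
                 ValidationError)

logger = logging.getLogger("agenet")

DE_COLUMNS = ["gene_id", "log2fc", "p_value", "adj_p", "direction", "significant"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    With p sorted ascending, ``q_(i) = min_{j>=i} p_(j) * m / j`` capped
    at 1. Output reordered by ascending p is monotone non-decreasing and
    ``q >= p`` elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _finalize(table: pd.DataFrame, adj_threshold: float) -> pd.DataFrame:
    table = table.copy()
    table["direction"] = np.where(table["log2fc"].to_numpy() > 0, "up", "down")
    table["significant"] = table["adj_p"].to_numpy() < adj_threshold
    # deterministic: adj_p, then p, then lexical gene id
    table = table.sort_values(["adj_p", "p_value", "gene_id"],
                              kind="mergesort").reset_index(drop=True)
    return table[DE_COLUMNS + [c for c in table.columns if c not in DE_COLUMNS]]


def builtin_de(tpm: ExpressionMatrix, meta: SampleMetadata,
               config: RunConfig) -> pd.DataFrame:
    """Welch t-test DE table for one tissue.

    Returns one row per gene: gene_id, log2fc (aging - young on the
    log2(TPM+1) scale), p_value, adj_p (BH across all genes of the
    tissue), direction, significant, zero_variance. Genes constant in
    both groups get p = 1 and are flagged. Rows sorted by (adj_p, p,
    gene id).
    """
    if tpm.unit != "tpm":
        raise ValidationError("builtin_de expects a TPM matrix")
    tissues = meta.tissues()
    if len(tissues) != 1:
        raise ValidationError(f"metadata must describe one tissue, got {tissues}")
    y_ids = meta.samples_in_group(YOUNG)
    a_ids = meta.samples_in_group(AGING)
    if len(y_ids) < 2 or len(a_ids) < 2:
        raise ValidationError("each group needs >= 2 samples for the t-test")

    log = np.log2(tpm.data.to_numpy(dtype=float) + 1.0)
    # median-of-ratios sample normalization against the mean gene profile
    ref = log.mean(axis=1, keepdims=True)
    log = log - np.median(log - ref, axis=0, keepdims=True)
    log_df = pd.DataFrame(log, index=tpm.gene_ids, columns=tpm.sample_ids)
    if config.batch_center:
        batches = meta.table.set_index("sample_id")["batch"]
        grand = log_df.mean(axis=1)
        for b in batches.unique():
            cols = list(batches.index[batches == b])
            sub = log_df[cols]
            log_df[cols] = sub.sub(sub.mean(axis=1) - grand, axis=0)
    y = log_df[y_ids].to_numpy()
    a = log_df[a_ids].to_numpy()

    log2fc = a.mean(axis=1) - y.mean(axis=1)
    res = stats.ttest_ind(a, y, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (y.var(axis=1) == 0) & (a.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    if zero_var.any():
        logger.warning("%d gene(s) constant in both groups; p set to 1",
                       int(zero_var.sum()))

    table = pd.DataFrame({
        "gene_id": tpm.gene_ids,
        "log2fc": log2fc,
        "p_value": p,
        "adj_p": bh_adjust(p),
        "zero_variance": zero_var,
    })
    return _finalize(table, config.de_adj_p)


def ingest_external_de(path: str | Path, config: RunConfig,
                       columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Adapt an externally computed DE table (e.g. from a count-based
    NB-GLM engine) to the internal schema.

    Expected columns (renameable via ``columns``): gene, log2FoldChange,
    pvalue, padj. Rows with missing padj are kept as not-significant with
    a logged warning.
    """
    names = {"gene": "gene", "log2fc": "log2FoldChange",
             "p": "pvalue", "padj": "padj"}
    if columns:
        names.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in names.values() if c not in df.columns]
    if missing:
        raise ValidationError(f"external DE table missing columns: {missing}")
    table = pd.DataFrame({
        "gene_id": df[names["gene"]].astype(str),
        "log2fc": pd.to_numeric(df[names["log2fc"]]),
        "p_value": pd.to_numeric(df[names["p"]]),
        "adj_p": pd.to_numeric(df[names["padj"]]),
    })
    na = table["adj_p"].isna()
    if na.any():
        logger.warning("%d row(s) with missing adjusted p treated as "
                       "not significant", int(na.sum()))
        table.loc[na, "adj_p"] = 1.0
    table["p_value"] = table["p_value"].fillna(1.0)
    table["log2fc"] = table["log2fc"].fillna(0.0)
    return _finalize(table, config.de_adj_p)


def significant_genes(de_table: pd.DataFrame) -> set[str]:
    """The DEG set of a tissue: significant regardless of direction."""
    return set(de_table.loc[de_table["significant"], "gene_id"])


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return df
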