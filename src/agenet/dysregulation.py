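"""Dysregulated-node (DN) scoring: change in co-expression degree with age.

For one tissue, the gene universe is the union of the young and aging
networks' node sets; a gene absent from one network contributes degree 0
there. ``delta = degree_aging - degree_young`` (positive-edge degrees).
Genes are ranked by |delta| descending — connectivity gains and losses
both count as dysregulation — with ties broken by lexical gene id, and
the top ``ceil(dn_fraction * N)`` are flagged as DNs (ceil guarantees at
least one DN for any non-empty universe).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RunConfig, ValidationError
from .network import CoexpressionNetwork

logger = logging.getLogger("agenet")

DN_COLUMNS = ["gene_id", "degree_young", "degree_aging", "delta", "abs_delta",
              "rank", "is_dn"]


def delta_degree(net_young: CoexpressionNetwork,
                 net_aging: CoexpressionNetwork,
                 normalize: bool = False) -> pd.DataFrame:
    """Unranked per-gene degree-change table over the union node universe.

    With ``normalize`` the degrees are divided by (network size - 1)
    before differencing, correcting for unequal network sizes between the
    groups; the default is the raw integer difference.
    """
    if net_young.tissue != net_aging.tissue:
        raise ValidationError(
            f"networks from different tissues: {net_young.tissue!r} vs "
            f"{net_aging.tissue!r}")
    universe = sorted(set(net_young.nodes) | set(net_aging.nodes))
    if not universe:
        return pd.DataFrame(columns=DN_COLUMNS[:-2])
    overlap = set(net_young.nodes) & set(net_aging.nodes)
    if not overlap and net_young.nodes and net_aging.nodes:
        logger.warning("tissue %s: young/aging node sets are disjoint — "
                       "expression filter instability", net_young.tissue)
    d_y = net_young.degree.reindex(universe, fill_value=0)
    d_a = net_aging.degree.reindex(universe, fill_value=0)
    if normalize:
        denom_y = max(len(net_young.nodes) - 1, 1)
        denom_a = max(len(net_aging.nodes) - 1, 1)
        delta = d_a / denom_a - d_y / denom_y
    else:
        delta = (d_a - d_y).astype(int)
    return pd.DataFrame({
        "gene_id": universe,
        "degree_young": d_y.to_numpy(),
        "degree_aging": d_a.to_numpy(),
        "delta": delta.to_numpy(),
        "abs_delta": np.abs(delta.to_numpy()),
    })


def select_dns(records: pd.DataFrame, dn_fraction: float = 0.10) -> pd.DataFrame:
    """Rank by |delta| (descending, lexical-id tie-break) and flag the top
    ceil(dn_fraction * N) genes as dysregulated nodes."""
    if not (0.0 < dn_fraction <= 1.0):
        raise ValidationError(f"dn_fraction must be in (0, 1], got {dn_fraction}")
    if len(records) == 0:
        out = records.copy()
        out["rank"] = pd.Series(dtype=int)
        out["is_dn"] = pd.Series(dtype=bool)
        return out
    out = records.sort_values(["abs_delta", "gene_id"],
                              ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    n = len(out)
    n_dn = math.ceil(dn_fraction * n)
    out["rank"] = np.arange(1, n + 1)
    out["is_dn"] = out["rank"] <= n_dn
    return out[DN_COLUMNS]


def dysregulation_table(net_young: CoexpressionNetwork,
                        net_aging: CoexpressionNetwork,
                        config: RunConfig) -> pd.DataFrame:
    return select_dns(delta_degree(net_young, net_aging,
                                   normalize=config.normalize_degree),
                      config.dn_fraction)


def dn_genes(table: pd.DataFrame) -> set[str]:
    if len(table) == 0:
        return set()
    return set(table.loc[table["is_dn"], "gene_id"])


def write_dn_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_dn_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_dn"] = df["is_dn"].astype(bool)
    return df
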