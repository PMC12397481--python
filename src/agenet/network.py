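"""Condition-specific Spearman co-expression networks.

One network is built per (tissue, age group): genes are kept when their
TPM summary over the condition's samples exceeds the expression threshold
(median > 5 by default), all C(n, 2) gene pairs are Spearman-correlated,
pair p-values are BH-adjusted across all tested pairs of the network, and
edges with q below the FDR threshold are retained. Degree centrality —
the statistic the dysregulation stage consumes — counts only the
*positive* retained edges of a gene; negative-edge degree is kept as a
diagnostic.

Spearman rho is the Pearson correlation of mid-ranks (average ranks for
ties). Pair p-values come, by default, from the *universal permutation
null*: at fixed n the null distribution of Spearman's rho does not depend
on the data, so one Monte-Carlo table of null |rho| values (fixed
internal seed, hence deterministic; size scaled to the number of tested
pairs so the far tail is resolved at BH depth) serves every pair of the
network. The classical two-sided t approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n - 2 df is available via
``edge_p_method="t"``, but it is measurably anticonservative in the far
tail that all-pairs BH actually thresholds (about 2x at p ~ 2.5e-6 for
n = 30), which inflates the realized edge FDR; the permutation p-value
is super-uniform by construction and restores control.

All-pairs computation is blocked: the rank matrix is
formed once and cross-correlation blocks of at most ``block_size`` rows
are produced at a time, so a panel-scale gene set never materializes the
full genes x genes correlation matrix. Results are identical to the naive
pair-at-a-time order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, RunConfig, ValidationError
from .diffexpr import bh_adjust

logger = logging.getLogger("agenet")

EDGE_COLUMNS = ["gene_a", "gene_b", "rho", "p", "q"]


@dataclass
class CoexpressionNetwork:
    """Significant-edge list and positive-edge degrees for one condition."""

    tissue: str
    group: str
    nodes: list[str]                      # genes passing the expression filter
    edges: pd.DataFrame = field(repr=False)  # gene_a < gene_b lexically
    degree: pd.Series = field(repr=False)     # positive-edge degree per node
    degree_neg: pd.Series = field(repr=False)  # diagnostic
    n_pairs_tested: int = 0
    n_pairs_skipped: int = 0              # constant-gene pairs, rho undefined

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if not (e["gene_a"] < e["gene_b"]).all():
                raise ValidationError("edges must be stored with gene_a < gene_b")
            if e.duplicated(["gene_a", "gene_b"]).any():
                raise ValidationError("duplicate edges")
            node_set = set(self.nodes)
            if not (e["gene_a"].isin(node_set).all()
                    and e["gene_b"].isin(node_set).all()):
                raise ValidationError("edge endpoints must be filtered nodes")

    @property
    def n_positive_edges(self) -> int:
        return int((self.edges["rho"] > 0).sum()) if len(self.edges) else 0


def filter_genes(tpm: ExpressionMatrix, sample_ids: list[str],
                 threshold: float = 5.0, rule: str = "median") -> list[str]:
    """Genes whose condition-level TPM summary strictly exceeds ``threshold``.

    ``rule`` selects the aggregation over the condition's samples:
    ``median`` (default, robust to outlier samples), ``mean``, or ``all``
    (every sample must exceed the threshold). Order of the returned list
    follows lexical gene id, so downstream output is input-order invariant.
    """
    if len(sample_ids) < 2:
        raise ValidationError("need >= 2 samples to filter/correlate")
    sub = tpm.subset_samples(sample_ids).data
    if rule == "median":
        summary = sub.median(axis=1)
    elif rule == "mean":
        summary = sub.mean(axis=1)
    elif rule == "all":
        summary = sub.min(axis=1)
    else:
        raise ValidationError(f"unknown filter rule {rule!r}")
    kept = sorted(summary.index[summary > threshold])
    if not kept:
        logger.warning("expression filter removed every gene (threshold %s)",
                       threshold)
    return kept


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation of two vectors with its t-approximation p-value.

    Mid-ranks (average ranks on ties) are Pearson-correlated; p is
    two-sided from ``t = rho*sqrt((n-2)/(1-rho^2))`` with n-2 df, and
    |rho| = 1 gives p = 0 exactly. Constant input is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need n >= 3 for a Spearman p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    return rho, _t_approx_p(np.array([rho]), n)[0]


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; exact +/-1 maps to 0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.minimum(p, 1.0)


# Monte-Carlo null tables keyed by (n_samples, table_size); ~64 MB each at
# the largest size used by a 200-gene network, so a small cache suffices.
_NULL_TABLE_SEED = 920_110_1
_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}
_NULL_CACHE_MAX = 4


def _null_table_size(n_pairs: int) -> int:
    """Enough null draws that >~100 land beyond the deepest BH threshold
    (0.05 / n_pairs at the reference FDR level), keeping order-statistic
    noise at the binding depth to a few percent. Deliberately independent
    of the configured edge_fdr so that tightening the FDR can only remove
    edges (the monotonicity contract). Bucketed so tables are shared
    across runs of similar size, and capped at 6.4e7 (256 MB as float32):
    the resolution floor 1/(M+1) still sits well below the
    single-discovery BH threshold of any network whose pair count fits in
    memory, and table build time stays around a minute."""
    need = 2500 * n_pairs
    for bucket in (4_000_000, 8_000_000, 16_000_000, 64_000_000):
        if need <= bucket:
            return bucket
    return 64_000_000


def _null_abs_rho(n: int, size: int) -> np.ndarray:
    """Sorted |rho| draws from the exact permutation null at sample size n.

    The null law of Spearman's rho for tie-free data is the correlation
    of a uniformly random permutation with the identity ranking — it
    depends on n only, so the table is shared by every pair and every
    network at this n. Fixed seed => bit-reproducible across runs.
    """
    key = (n, size)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence([_NULL_TABLE_SEED, n, size]))
    e = (np.arange(n, dtype=np.float32) - (n - 1) / 2.0)
    c2 = float(e.astype(float) @ e.astype(float))
    out = np.empty(size, dtype=np.float32)
    chunk = 1_000_000
    base = np.tile(np.arange(n, dtype=np.float32) - (n - 1) / 2.0, (chunk, 1))
    for start in range(0, size, chunk):
        k = min(chunk, size - start)
        perms = rng.permuted(base[:k], axis=1)
        out[start:start + k] = (perms @ e) / np.float32(c2)
    np.abs(out, out=out)
    out.sort(kind="stable")
    if len(_NULL_CACHE) >= _NULL_CACHE_MAX:
        _NULL_CACHE.pop(next(iter(_NULL_CACHE)))
    _NULL_CACHE[key] = out
    return out


_MC_CONFIDENCE = 0.975


def _permutation_p(rho: np.ndarray, n: int, n_pairs: int) -> np.ndarray:
    """Two-sided permutation p from the shared null table.

    Reported as the 97.5% Clopper-Pearson upper confidence limit of the
    true tail probability given ``k`` table exceedances out of ``M``
    draws, rather than the point estimate ``(k+1)/(M+1)``: the BH step
    thresholds these p-values in a region where ``k`` is a few dozen, so
    the point estimate carries enough Monte-Carlo noise to perturb FDR
    control, while the upper limit is insensitive to it at a negligible
    power cost (for a clearly real edge ``k = 0`` and the limit is
    ~3.7/M, far below any BH threshold in use).
    """
    size = _null_table_size(n_pairs)
    table = _null_abs_rho(n, size)
    exceed = size - np.searchsorted(table, np.abs(rho).astype(np.float32),
                                    side="left")
    uniq, inverse = np.unique(exceed, return_inverse=True)
    p_uniq = stats.beta.isf(1.0 - _MC_CONFIDENCE, uniq + 1.0,
                            np.maximum(size - uniq, 1e-12))
    p_uniq = np.where(uniq >= size, 1.0, p_uniq)
    return np.minimum(p_uniq[inverse], 1.0)


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered, L2-normalized mid-ranks per row; flags constant rows."""
    ranks = stats.rankdata(values, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def build_network(tpm: ExpressionMatrix, sample_ids: list[str],
                  config: RunConfig, tissue: str = "", group: str = "",
                  block_size: int = 512) -> CoexpressionNetwork:
    """Build the co-expression network of one (tissue, group) condition.

    All pairs of filtered genes are tested; BH runs across exactly those
    pairs; edges with q < ``config.edge_fdr`` are kept (both signs
    stored). Deterministic and invariant to gene/sample input order.
    """
    nodes = filter_genes(tpm, sample_ids, config.tpm_filter_threshold,
                         config.filter_rule)
    empty = pd.DataFrame(columns=EDGE_COLUMNS)
    if len(nodes) < 2:
        logger.warning("network %s/%s: fewer than 2 nodes pass the filter",
                       tissue, group)
        deg = pd.Series(0, index=nodes, dtype=int)
        return CoexpressionNetwork(tissue, group, nodes, empty, deg, deg.copy())

    sub = tpm.subset_samples(sample_ids).data.loc[nodes]
    values = sub.to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValidationError("need >= 3 samples for edge p-values")
    ranks, constant = _rank_rows(values)
    if constant.any():
        logger.warning("network %s/%s: %d constant gene(s) — their pairs are "
                       "skipped", tissue, group, int(constant.sum()))

    p_count = len(nodes)
    ia_parts, ib_parts, rho_parts = [], [], []
    n_skipped = 0
    for start in range(0, p_count, block_size):
        stop = min(start + block_size, p_count)
        # correlations of rows [start, stop) against all rows
        block = ranks[start:stop] @ ranks.T
        for i in range(start, stop):
            js = np.arange(i + 1, p_count)
            if js.size == 0:
                continue
            ok = ~(constant[i] | constant[js])
            n_skipped += int((~ok).sum())
            js = js[ok]
            if js.size == 0:
                continue
            ia_parts.append(np.full(js.size, i, dtype=np.int32))
            ib_parts.append(js.astype(np.int32))
            rho_parts.append(block[i - start, js])

    if not ia_parts:
        deg = pd.Series(0, index=nodes, dtype=int)
        return CoexpressionNetwork(tissue, group, nodes, empty, deg, deg.copy(),
                                   0, n_skipped)
    ia = np.concatenate(ia_parts)
    ib = np.concatenate(ib_parts)
    rho = np.clip(np.concatenate(rho_parts), -1.0, 1.0)
    n_tested = ia.size
    if config.edge_p_method == "permutation":
        p = _permutation_p(rho, n_samples, n_tested)
    else:
        p = _t_approx_p(rho, n_samples)
    q = bh_adjust(p)

    keep = q < config.edge_fdr
    node_arr = np.array(nodes)
    edges = pd.DataFrame({
        "gene_a": node_arr[ia[keep]],
        "gene_b": node_arr[ib[keep]],
        "rho": rho[keep],
        "p": p[keep],
        "q": q[keep],
    }).sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)

    degree = pd.Series(0, index=nodes, dtype=int)
    degree_neg = pd.Series(0, index=nodes, dtype=int)
    if len(edges):
        pos = edges[edges["rho"] > 0]
        neg = edges[edges["rho"] <= 0]
        for col in ("gene_a", "gene_b"):
            degree = degree.add(pos[col].value_counts(), fill_value=0)
            degree_neg = degree_neg.add(neg[col].value_counts(), fill_value=0)
        degree = degree.astype(int)
        degree_neg = degree_neg.astype(int)

    return CoexpressionNetwork(tissue, group, nodes, edges, degree, degree_neg,
                               n_tested, n_skipped)


def degree_centrality(network: CoexpressionNetwork,
                      positive_only: bool = True) -> pd.Series:
    """Per-node count of incident retained edges (positive edges only by
    default, matching the dysregulation statistic)."""
    if positive_only:
        return network.degree.copy()
    return (network.degree + network.degree_neg).astype(int)


def write_edges(network: CoexpressionNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def write_degrees(network: CoexpressionNetwork, path: str | Path) -> None:
    pd.DataFrame({
        "gene_id": network.nodes,
        "degree_pos": network.degree.reindex(network.nodes).to_numpy(),
        "degree_neg": network.degree_neg.reindex(network.nodes).to_numpy(),
    }).to_csv(path, sep="\t", index=False)
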