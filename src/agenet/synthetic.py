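"""Synthetic multi-tissue two-group expression cohorts with known truth.

The generator emulates the structure of a bulk RNA-seq aging cohort: two
age groups (young/aging), negative-binomial read counts per tissue, TPM
recomputed from counts, balanced batch labels, and two kinds of planted
signal that the downstream stages are meant to recover:

* **Planted DE genes** — a ``de_log2fc`` shift of the aging-group mean on
  the log2 expression scale.
* **Planted co-expression modules** — blocks of genes sharing a latent
  per-sample factor, whose *loading* differs between groups, so module
  connectivity (and hence co-expression degree) changes with age.

Generative model for the log2 expression signal of gene ``g`` in sample
``s`` of group ``k``::

    signal = b_g + L_mk * f_ms + eps,   b_g ~ N(mu0, sd0),  f_ms ~ N(0, 1)

where ``L_mk`` is the loading of gene g's module m in group k (0 for
non-module genes) and the residual sd is ``sqrt(1 - L_mk^2)`` for module
genes and 1 for the rest, so every gene has unit marginal latent variance
and the population correlation between two genes of the same module is
exactly ``L_mk**2``. Planted DE shifts are added to the aging mean, batch
offsets (per gene x batch) on top. The signal is mapped to an expected
within-sample expression fraction ``2**signal / sum_g 2**signal`` and
counts are drawn NB(mean = fraction * library_size, Var = mu + a*mu^2)
with shared dispersion ``a``. TPM is then recomputed from the counts under
the default unit gene length.

Everything is deterministic given ``(config, tissue_index)``: the tissue
index is folded into the seed stream, and planted gene positions are fixed
by the config (module genes first, then DE genes), so the same gene ids
carry the signal in every tissue of a panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AGING, YOUNG, ExpressionMatrix, SampleMetadata, ValidationError


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort (shared across its tissues)."""

    n_genes: int = 300
    n_tissues: int = 5
    n_young: int = 30
    n_aging: int = 30
    n_de_genes: int = 20
    de_log2fc: float = 2.0
    module_sizes: tuple[int, ...] = (20,)
    loading_young: tuple[float, ...] = (0.9,)
    loading_aging: tuple[float, ...] = (0.0,)
    module_de_log2fc: float = 0.0
    nb_dispersion: float = 0.1
    baseline_log2_tpm_mean: float = 5.0
    baseline_log2_tpm_sd: float = 1.0
    batch_effect_sd: float = 0.0
    library_size_mean: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_aging < 2:
            raise ValidationError("need >= 2 samples per group (correlations undefined)")
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ValidationError("n_genes and n_tissues must be positive")
        if self.n_de_genes < 0:
            raise ValidationError("n_de_genes must be >= 0")
        if len(self.module_sizes) != len(self.loading_young) or \
                len(self.module_sizes) != len(self.loading_aging):
            raise ValidationError("one loading per module per group required")
        if any(m < 1 for m in self.module_sizes):
            raise ValidationError("module sizes must be positive")
        if self.n_de_genes + sum(self.module_sizes) > self.n_genes:
            raise ValidationError("planted genes exceed n_genes (must be disjoint)")
        for L in (*self.loading_young, *self.loading_aging):
            if not 0.0 <= L <= 1.0:
                raise ValidationError(f"loadings must be in [0,1], got {L}")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.batch_effect_sd < 0 or self.library_size_mean <= 0:
            raise ValidationError("batch_effect_sd >= 0 and library_size_mean > 0 required")

    def null(self) -> "CohortConfig":
        """A global-null variant: no DE shift, loadings equal across groups."""
        return replace(self, de_log2fc=0.0, module_de_log2fc=0.0,
                       loading_aging=self.loading_young)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to each tissue's matrices."""

    de_genes: dict[str, int]            # planted pure-DE gene -> sign of log2fc
    module_assignments: dict[str, int]  # module gene -> module index
    connectivity_delta_genes: set[str]  # module genes whose loading differs
    shifted_genes: dict[str, int]       # all genes with a planted mean shift
    batch_labels: dict[str, str]        # sample id -> batch

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.de_genes) | set(self.module_assignments))
        return pd.DataFrame({
            "gene_id": genes,
            "is_de": [g in self.shifted_genes for g in genes],
            "de_sign": [self.shifted_genes.get(g, 0) for g in genes],
            "module": [self.module_assignments.get(g, -1) for g in genes],
            "connectivity_delta": [g in self.connectivity_delta_genes for g in genes],
        })


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_tissue(config: CohortConfig, tissue_index: int,
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                               SampleMetadata, SyntheticTruth]:
    """Generate one tissue of the cohort: (counts, TPM, metadata, truth)."""
    if tissue_index >= config.n_tissues or tissue_index < 0:
        raise ValidationError(
            f"tissue_index {tissue_index} out of range [0, {config.n_tissues})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, tissue_index]))

    tissue = f"tissue{tissue_index:02d}"
    genes = _gene_ids(config.n_genes)
    n_y, n_a = config.n_young, config.n_aging
    n = n_y + n_a
    samples = [f"{tissue}.Y{j:03d}" for j in range(n_y)] + \
              [f"{tissue}.A{j:03d}" for j in range(n_a)]
    groups = np.array([YOUNG] * n_y + [AGING] * n_a)

    # planted gene layout: modules first, then pure-DE genes (disjoint)
    module_of = np.full(config.n_genes, -1)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_of[pos:pos + size] = m
        pos += size
    de_idx = np.arange(pos, pos + config.n_de_genes)

    baselines = rng.normal(config.baseline_log2_tpm_mean,
                           config.baseline_log2_tpm_sd, size=config.n_genes)

    signal = np.tile(baselines[:, None], (1, n)).astype(float)
    # latent module factors and residuals; unit marginal variance throughout
    n_mod = len(config.module_sizes)
    factors = rng.normal(size=(n_mod, n)) if n_mod else np.empty((0, n))
    eps = rng.normal(size=(config.n_genes, n))
    loadings = np.zeros((config.n_genes, n))
    for m in range(n_mod):
        in_m = module_of == m
        L = np.where(groups == YOUNG, config.loading_young[m],
                     config.loading_aging[m])
        loadings[in_m] = L
        signal[in_m] += L * factors[m]
    signal += eps * np.sqrt(1.0 - loadings ** 2)

    aging_mask = groups == AGING
    signal[np.ix_(de_idx, np.where(aging_mask)[0])] += config.de_log2fc
    if config.module_de_log2fc:
        mod_idx = np.where(module_of >= 0)[0]
        signal[np.ix_(mod_idx, np.where(aging_mask)[0])] += config.module_de_log2fc

    # two balanced batches within each group: batch never confounds age
    batch = np.empty(n, dtype=object)
    for mask in (~aging_mask, aging_mask):
        idx = np.where(mask)[0]
        half = len(idx) // 2
        batch[idx[:half]] = "b1"
        batch[idx[half:]] = "b2"
    if config.batch_effect_sd > 0:
        for b in ("b1", "b2"):
            offset = rng.normal(0.0, config.batch_effect_sd, size=config.n_genes)
            signal[:, batch == b] += offset[:, None]

    # NB counts: mean = within-sample expression fraction * library size
    rel = np.exp2(signal)
    frac = rel / rel.sum(axis=0, keepdims=True)
    lib = rng.lognormal(math.log(config.library_size_mean), 0.1, size=n)
    mu = np.maximum(frac * lib, 1e-12)
    a = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / a, scale=a * mu)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_mat = ExpressionMatrix(counts_df, "counts")
    tpm_mat = counts_to_tpm(counts_mat)

    meta = SampleMetadata(pd.DataFrame({
        "sample_id": samples,
        "group": groups,
        "tissue": tissue,
        "batch": batch,
    }))

    sign = int(np.sign(config.de_log2fc)) if config.de_log2fc else 0
    msign = int(np.sign(config.module_de_log2fc)) if config.module_de_log2fc else 0
    de_genes = {genes[i]: sign for i in de_idx} if sign else {genes[i]: 0 for i in de_idx}
    modules = {genes[i]: int(module_of[i])
               for i in range(config.n_genes) if module_of[i] >= 0}
    conn = {g for g, m in modules.items()
            if config.loading_young[m] != config.loading_aging[m]}
    shifted = dict(de_genes) if sign else {}
    if msign:
        shifted.update({g: msign for g in modules})
    truth = SyntheticTruth(
        de_genes=de_genes,
        module_assignments=modules,
        connectivity_delta_genes=conn,
        shifted_genes=shifted,
        batch_labels=dict(zip(samples, batch)),
    )
    return counts_mat, tpm_mat, meta, truth


def generate_panel(config: CohortConfig) -> dict[str, tuple[ExpressionMatrix,
                                                            ExpressionMatrix,
                                                            SampleMetadata,
                                                            SyntheticTruth]]:
    """All tissues of the cohort, keyed by tissue name."""
    out = {}
    for t in range(config.n_tissues):
        counts, tpm, meta, truth = generate_tissue(config, t)
        out[meta.table["tissue"].iloc[0]] = (counts, tpm, meta, truth)
    return out


def counts_to_tpm(counts: ExpressionMatrix,
                  lengths_kb: dict[str, float] | None = None) -> ExpressionMatrix:
    """Standard TPM from a counts matrix.

    ``rate_g = count_g / length_g``; ``TPM_g = 1e6 * rate_g / sum_g rate_g``
    per sample. Gene lengths default to 1 kb (TPM proportional to the
    count share). A sample with all-zero counts has no defined TPM.
    """
    if counts.unit != "counts":
        raise ValidationError("counts_to_tpm expects a counts matrix")
    if lengths_kb is None:
        lens = np.ones(counts.shape[0])
    else:
        missing = [g for g in counts.gene_ids if g not in lengths_kb]
        if missing:
            raise ValidationError(f"missing gene lengths: {missing[:5]}")
        lens = np.array([lengths_kb[g] for g in counts.gene_ids], dtype=float)
        if (lens <= 0).any():
            raise ValidationError("gene lengths must be positive")
    rate = counts.data.to_numpy(dtype=float) / lens[:, None]
    colsum = rate.sum(axis=0)
    zero = np.where(colsum == 0)[0]
    if len(zero):
        raise ValidationError(
            f"all-zero sample(s), TPM undefined: {[counts.sample_ids[i] for i in zero[:5]]}")
    tpm = 1e6 * rate / colsum
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids), "tpm")


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
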