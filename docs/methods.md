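# Methods

## Pipeline overview

For each tissue with more than `min_samples_per_group` (default 10,
strict) samples in *both* age groups, the pipeline runs:

1. differential expression between aging and young samples;
2. one co-expression network per age group;
3. the delta-degree dysregulated-node (DN) statistic with top-10 %
   selection;

then aggregates across tissues:

4. Single/Some/Many categorization of per-gene DEG and DN tissue counts
   and the DEG-Many ∩ DN-Many core biomarker set;
5. random-forest age-group classification on the core set, per-tissue
   refits, and a composite model over pooled tissues.

All thresholds live in `RunConfig`; the defaults (TPM filter 5, edge FDR
0.05, DE adjusted-p 0.05, DN fraction 0.10, Many ≥ 14 tissues, 1000
trees, 70/30 split) are the standard constants of this analysis design.

## Differential expression

The built-in test is a per-gene Welch two-sample t-test on
log2(TPM + 1), with Benjamini–Hochberg adjustment across the genes of
one tissue. The log2 fold change is aging − young on that scale;
direction is its sign with no magnitude cutoff; significance is
adjusted p < `de_adj_p`. Genes constant in both groups get p = 1 and a
`zero_variance` flag. Output rows are sorted by (adjusted p, p, gene id)
for determinism.

Because TPM is compositional, strong planted (or real) changes in a gene
subset deflate all other genes' TPM and would masquerade as widespread
opposite-direction change. `builtin_de` therefore first applies a
median-of-ratios sample normalization — each sample's log2(TPM+1) column
is shifted by the median, over genes, of its deviation from the
gene-wise mean profile — the same idea count-based DE engines use for
size factors. Under a balanced null the shift is ≈ 0; under asymmetric
change it removes the compositional offset because the median gene is
unaffected. Cohorts analysed with an external count-based NB-GLM engine
can be ingested through `ingest_external_de`, which applies the same
significance/direction semantics to a (gene, log2FoldChange, pvalue,
padj) table; missing padj is treated as not-significant with a warning.

Batch handling: `builtin_de` optionally mean-centers log2(TPM+1) per
batch before testing (`batch_center`, off by default). The synthetic
generator emits balanced batch labels, so batch is never confounded with
age group in simulated cohorts.

## Co-expression networks and edge significance

Per condition (tissue × age group), genes pass the expression filter
when their **median** TPM over the condition's samples strictly exceeds
`tpm_filter_threshold`. Median (rather than mean or all-samples) is the
default because it is robust to single outlier samples; both
alternatives are available via `filter_rule`. The filter is applied
independently per condition, matching the separately built young/aging
networks.

All C(n, 2) pairs of filtered genes are Spearman-correlated (mid-rank
Pearson, computed by blocked matrix products over the rank matrix so the
full gene × gene matrix is never materialized; results are identical to
the naive pair order). BH runs across exactly the tested pairs of one
network — the narrowest defensible family — and edges with q <
`edge_fdr` are retained with both signs stored. Degree centrality counts
only positive retained edges; negative-edge degree is kept as a
diagnostic. Constant genes stay in the node set but their pairs are
skipped and tallied.

**Edge p-values.** The classical t approximation
t = ρ·√((n−2)/(1−ρ²)) is exposed (`edge_p_method="t"`, and it is the
contract of the single-pair `spearman_rho` helper), but all-pairs BH
thresholds p-values at depths around `edge_fdr / n_pairs` (~10⁻⁶ for a
200-gene network), where direct measurement shows the t approximation is
about 2× anticonservative at n = 30 (and the Fisher-z approximation
about 3.5×), inflating the realized false-edge rate well beyond the
nominal level. The default (`edge_p_method="permutation"`) therefore
uses the *universal permutation null*: for tie-free data the null law of
Spearman's ρ at fixed n is the correlation of a random permutation with
the identity ranking — independent of the data — so one Monte-Carlo
table of null |ρ| values serves every pair of the network. The table is
generated from a fixed internal seed (bit-reproducible), sized to the
tested pair count (≈ 2500 draws per pair, bucketed, capped at 6.4 × 10⁷
≙ 256 MB float32) so that ≥ ~100 draws resolve the deepest BH threshold,
and shared across networks via an in-process cache. The reported p-value
is the 97.5 % Clopper–Pearson upper confidence limit of the tail
probability given the table counts, not the point estimate: at the
binding depth the count is small enough that point-estimate noise would
perturb FDR control, while the upper limit is insensitive to it at
negligible power cost (a clearly real edge has zero exceedances and
p ≈ 3.7/M, far below any BH threshold in use). Table size is
deliberately independent of the configured `edge_fdr`, so tightening the
FDR can only remove edges (monotonicity). The universal null assumes no
ties; TPM from realistic count depths makes ties vanishingly rare, and
mid-ranks keep ρ itself exact under ties.

With this construction, the realized probability that a global-null
200-gene network (n = 30) yields any false edge at `edge_fdr = 0.05`
matches the BH guarantee (measured 0.06 over 300 simulated cohorts
against the theoretical 0.05); note that any single batch of a few dozen
null cohorts estimates this rate with sampling error of a few
hundredths.

## Dysregulated nodes

The gene universe of one tissue is the union of the young and aging
node sets; genes missing from one network contribute degree 0 there
(the only set on which the statistic is defined — genes never passing
any filter are excluded). Δ = deg_aging − deg_young; ranking is by |Δ|
descending — connectivity gains and losses both count as dysregulation —
with ties broken by lexical gene id, and the top ⌈`dn_fraction` · N⌉
genes are flagged (ceil guarantees ≥ 1 DN for any non-empty universe).
Raw degree differences are the default; `normalize_degree` divides each
degree by (network size − 1) to correct for unequal network sizes
between groups. No significance is attached to Δ; the top-10 % rule is a
selection, not a test, and under a global null the selected set is
arbitrary (the tests verify exactly that, as a negative control).

## Cross-tissue atlas

Per gene, the number of tissues where it is a significant DEG and where
it is a DN maps to categories: 0 → none, 1 → single,
[`some_min_tissues`, `many_min_tissues`) → some, ≥ `many_min_tissues` →
many. The default Many boundary is 14: with Some defined as 2–13, a
boundary of 15 would leave a count of 14 unclassifiable, so 14 is the
only exhaustive choice; it is configurable. DEG membership counts
significant genes regardless of direction. Percentages are computed over
the ever-detected universe (genes tested in ≥ 1 tissue). The core
biomarker set is the exact intersection of the DEG-Many and DN-Many
sets, sorted lexically.

## Classifier

Features are log2(TPM + 1) per gene (monotone transforms do not affect
tree splits; the log keeps reported importances comparable with the DE
scale). The split is stratified by age group — the proportions rule
alone would allow degenerate test sets at small n — and the forest is
1000 trees, bootstrap on, out-of-bag scoring on, all other
hyperparameters at scikit-learn defaults (recorded verbatim in the
report). AUC and accuracy are computed on the held-out 30 % only; the
OOB score is reported alongside as the bootstrap-internal estimate.
Importances are mean impurity decrease normalized to sum to 1; ranking
ties break lexically. Per-tissue evaluation refits one forest per tissue
on the shared top-feature list (tissues that cannot support a stratified
fit are skipped with a log entry). The composite predictor takes the
union of per-tissue top-feature lists and pools the tissues' samples;
expression is z-scored within tissue before pooling so that tissue
identity (via baseline expression differences) cannot leak into the
model as a proxy for group composition — `rf_zscore_composite` disables
this.

## Synthetic cohorts

The generator emulates a two-group multi-tissue bulk RNA-seq cohort. Per
tissue, the log2 expression signal of gene g in sample s of group k is

    signal = b_g + L_mk · f_ms + ε,  b_g ~ N(μ₀, σ₀),  f_ms ~ N(0, 1)

with module loading L_mk ∈ [0, 1] (0 for non-module genes) and residual
sd √(1 − L²) for module genes, 1 otherwise — so the latent marginal
variance is 1 for every gene and the population correlation between two
same-module genes is exactly L². Planted DE genes add `de_log2fc` to the
aging mean; `module_de_log2fc` does the same for module genes, letting a
cohort plant genes that are simultaneously differentially expressed and
connectivity-changed (the designated `n_de_genes` set stays disjoint
from modules). Signals map to within-sample expression fractions
2^signal / Σ 2^signal; counts are negative-binomial with mean =
fraction × library size and Var = μ + a·μ² (shared dispersion a, default
0.1 — moderate bulk-RNA-seq overdispersion); library sizes are
log-normal around `library_size_mean` (σ = 0.1); TPM is recomputed from
counts under unit gene lengths (a supplied length table switches
`counts_to_tpm` to the full rate formula). Batch labels split each group
evenly into two batches; `batch_effect_sd` defaults to 0 because
per-gene batch offsets induce genuine inter-gene correlation (a shared
two-point mixture), which would make "global null" cohorts not null for
network analysis — switching it on is an explicit confounding
experiment, not part of the null. Everything is deterministic given
(config, tissue index): the tissue index is folded into the seed stream,
and planted gene positions are fixed by the config, so the same gene ids
carry signal in every tissue of a panel.

What the generator does *not* model: realistic between-gene covariance
beyond the planted modules, GC/length biases, sex chromosomes, RNA
degradation, or age as a continuous variable. Recovery results on these
cohorts therefore demonstrate that the pipeline's statistics behave as
designed (calibrated nulls, recoverable planted effects); they do not
calibrate expected effect sizes in real tissue panels, for which no
public ground truth exists at this design.

## Problem sizes and runtime choices

Test and validation experiments run at desk scale, chosen so each stage
still operates in its intended regime: 200–520 genes per network
(19 900–134 940 pairs, enough for BH to threshold in the far tail),
30–60 samples per group (the order of real per-tissue group sizes),
15-tissue panels for cross-tissue categorization, and 5–50 replicate
cohorts per Monte-Carlo estimate. The all-pairs engine streams blocks of
pairs, so panel-scale inputs (tens of thousands of genes) change memory
by the pair vector only, not by a genes × genes matrix.

## Known limitations

- The Welch-on-log2(TPM+1) test is a stand-in for a count-based NB-GLM
  engine; it shares its significance/direction semantics but not its
  dispersion shrinkage or covariate modelling. Use the external-results
  adapter for production DE tables.
- Permutation edge p-values assume exchangeable samples within a
  condition; strong within-condition structure (e.g. unmodelled batches)
  violates this, as it does for any correlation test.
- The DN statistic inherits the instability of degree under filter
  boundaries: a gene near the TPM threshold can enter one group's
  network only. The union-universe convention makes this explicit
  (degree 0 on the missing side) rather than hiding it.
- Single/Some/Many boundaries are panel-width-dependent; for panels much
  narrower than ~40 tissues, `many_min_tissues` must be rescaled (the
  demo uses 4 of 5 tissues).
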