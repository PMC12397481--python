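"""End-to-end orchestration over a tissue panel.

``run_all`` drives the full analysis from files on disk: per tissue it
runs differential expression, builds the young and aging co-expression
networks, scores dysregulated nodes; it then aggregates the cross-tissue
atlas, intersects DEG-Many with DN-Many into the core biomarker set, and
fits the random-forest stage (overall model on the core set, per-tissue
AUCs, and — given at least two tissues — the composite predictor pooling
per-tissue top features). A manifest records the config snapshot, seed,
and the path + SHA-256 of every output, so a rerun with identical inputs
and seed is verifiable as bit-identical.

Expected ``data_dir`` layout: ``metadata.tsv`` (sample_id, group, tissue,
batch) plus ``<tissue>.tpm.tsv`` (and optionally ``<tissue>.counts.tsv``)
for every tissue in the metadata.

Per-stage random streams are derived from the master seed by stable
hashing of (seed, stage, tissue), so per-tissue stages could run in any
order — or concurrently — with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import classifier as clf_mod
from . import diffexpr, dysregulation, network
from .io import (AGING, YOUNG, RunConfig, SampleMetadata,
                 ValidationError, check_group_sizes, read_expression,
                 read_metadata, write_expression, write_metadata)
from .synthetic import CohortConfig, generate_panel, write_truth

logger = logging.getLogger("agenet")

VERSION = "0.1.0"


def derive_seed(master: int, *parts) -> int:
    """Stable per-stage substream seed: hash of (master, parts), < 2^31."""
    key = repr((int(master), *map(str, parts))).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Config snapshot + per-stage output paths and content hashes."""

    def __init__(self, config: RunConfig, out_dir: Path) -> None:
        self.out_dir = Path(out_dir)
        self.data = {
            "tool": "agenet", "version": VERSION,
            "config": config.to_dict(),
            "seed": config.seed,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "skipped_tissues": {},
            "outputs": {},
        }

    def record(self, stage: str, path: Path) -> None:
        self.data["outputs"][str(path.relative_to(self.out_dir))] = {
            "stage": stage, "sha256": _sha256(path)}

    def skip(self, tissue: str, reason: str) -> None:
        self.data["skipped_tissues"][tissue] = reason

    def finish(self) -> Path:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path

    @property
    def output_hashes(self) -> dict[str, str]:
        return {k: v["sha256"] for k, v in self.data["outputs"].items()}


def run_all(config: RunConfig, data_dir: str | Path,
            out_dir: str | Path) -> Manifest:
    """Run the complete pipeline over every tissue in ``data_dir``."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, out_dir)

    meta = read_metadata(data_dir / "metadata.tsv")
    passing = check_group_sizes(meta, config)
    tissues = [t for t in meta.tissues() if passing[t]]
    for t in meta.tissues():
        if not passing[t]:
            sizes = meta.group_sizes(t)
            manifest.skip(t, f"group sizes {sizes} not > "
                             f"{config.min_samples_per_group} per group")
    if not tissues:
        raise ValidationError("no tissue passes the group-size check")

    deg_sets: dict[str, set[str]] = {}
    dn_sets: dict[str, set[str]] = {}
    universe: set[str] = set()
    tissue_tpm: dict[str, tuple[pd.DataFrame, pd.Series]] = {}

    for tissue in tissues:
        logger.info("tissue %s: DE + networks + DN", tissue)
        tpm = read_expression(data_dir / f"{tissue}.tpm.tsv", "tpm")
        t_meta = meta.for_tissue(tissue)
        universe |= set(tpm.gene_ids)
        labels = t_meta.table.set_index("sample_id")["group"]
        tissue_tpm[tissue] = (tpm.data, labels)

        de = diffexpr.builtin_de(tpm, t_meta, config)
        p = out_dir / f"{tissue}.de.tsv"
        diffexpr.write_de_table(de, p)
        manifest.record("de", p)
        deg_sets[tissue] = diffexpr.significant_genes(de)

        nets = {}
        for group in (YOUNG, AGING):
            net = network.build_network(
                tpm, t_meta.samples_in_group(group), config,
                tissue=tissue, group=group)
            nets[group] = net
            p = out_dir / f"{tissue}.{group}.edges.tsv"
            network.write_edges(net, p)
            manifest.record("network", p)
            p = out_dir / f"{tissue}.{group}.degrees.tsv"
            network.write_degrees(net, p)
            manifest.record("network", p)

        dn = dysregulation.dysregulation_table(nets[YOUNG], nets[AGING], config)
        p = out_dir / f"{tissue}.dn.tsv"
        dysregulation.write_dn_table(dn, p)
        manifest.record("dysregulation", p)
        dn_sets[tissue] = dysregulation.dn_genes(dn)

    atlas = atlas_mod.build_atlas(deg_sets, dn_sets, config, universe=universe)
    p = out_dir / "atlas.tsv"
    atlas_mod.write_atlas(atlas, p)
    manifest.record("atlas", p)
    p = out_dir / "summary.json"
    atlas_mod.write_summary(atlas, p)
    manifest.record("atlas", p)

    core = atlas_mod.core_biomarker_set(atlas)
    logger.info("core biomarker set: %d gene(s)", len(core))
    if len(core) >= 2:
        _classifier_stage(core, tissue_tpm, config, out_dir, manifest)
    else:
        logger.warning("core set too small (%d); classifier stage skipped",
                       len(core))

    manifest.finish()
    return manifest


def _classifier_stage(core: list[str],
                      tissue_tpm: dict[str, tuple[pd.DataFrame, pd.Series]],
                      config: RunConfig, out_dir: Path,
                      manifest: Manifest) -> clf_mod.ClassifierReport:
    """Overall model on the pooled core-set features, per-tissue AUCs,
    and the composite predictor over per-tissue top feature lists."""
    blocks, label_blocks = [], []
    for tissue in sorted(tissue_tpm):
        tpm_data, labels = tissue_tpm[tissue]
        feats = clf_mod.feature_table(tpm_data, core, warn_missing=False)
        if config.rf_zscore_composite:
            sd = feats.std(axis=0, ddof=0).replace(0.0, 1.0)
            feats = (feats - feats.mean(axis=0)) / sd
        blocks.append(feats)
        label_blocks.append(labels.reindex(feats.index))
    pooled = pd.concat(blocks)
    pooled_labels = pd.concat(label_blocks)
    overall = clf_mod.fit_rf(pooled, pooled_labels, config,
                             seed=derive_seed(config.seed, "rf", "overall"))
    for p in clf_mod.write_report(overall, out_dir, prefix="overall"):
        manifest.record("classifier", p)

    top = clf_mod.rank_features(overall, config.rf_top_k)
    per_tissue_top: dict[str, list[str]] = {}
    aucs = {}
    for tissue in sorted(tissue_tpm):
        try:
            tpm_data, labels = tissue_tpm[tissue]
            feats = clf_mod.feature_table(tpm_data, top, warn_missing=False)
            rep = clf_mod.fit_rf(feats, labels, config,
                                 seed=derive_seed(config.seed, "rf", tissue))
            aucs[tissue] = rep.auc
            per_tissue_top[tissue] = clf_mod.rank_features(
                rep, min(10, len(rep.top_features)))
        except ValidationError as exc:
            logger.warning("per-tissue classifier skipped for %s: %s",
                           tissue, exc)
    p = out_dir / "per_tissue_auc.tsv"
    pd.Series(aucs, name="auc").rename_axis("tissue").reset_index() \
        .to_csv(p, sep="\t", index=False)
    manifest.record("classifier", p)

    if len(per_tissue_top) >= 2:
        composite = clf_mod.composite_predictor(
            per_tissue_top, tissue_tpm, config,
            seed=derive_seed(config.seed, "rf", "composite"))
        for p in clf_mod.write_report(composite, out_dir, prefix="composite"):
            manifest.record("classifier", p)
    return overall


# ---------------------------------------------------------------------------
# Synthetic panel I/O and the one-command demo
# ---------------------------------------------------------------------------

def simulate_panel(config: CohortConfig, data_dir: str | Path,
                   write_counts: bool = True) -> None:
    """Generate a cohort and write it in the ``run_all`` data layout."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    meta_frames = []
    for tissue, (counts, tpm, meta, truth) in generate_panel(config).items():
        if write_counts:
            write_expression(counts, data_dir / f"{tissue}.counts.tsv")
        write_expression(tpm, data_dir / f"{tissue}.tpm.tsv")
        write_truth(truth, data_dir / f"{tissue}.truth.tsv")
        meta_frames.append(meta.table)
    merged = SampleMetadata(pd.concat(meta_frames, ignore_index=True))
    write_metadata(merged, data_dir / "metadata.tsv")


DEMO_COHORT = CohortConfig(
    n_genes=300, n_tissues=5, n_young=30, n_aging=30,
    n_de_genes=20, de_log2fc=2.0,
    module_sizes=(20,), loading_young=(0.9,), loading_aging=(0.0,),
    module_de_log2fc=2.0, nb_dispersion=0.1)

DEMO_RUN = RunConfig(many_min_tissues=4, some_min_tissues=2,
                     min_samples_per_group=10)


def demo(seed: int, out_dir: str | Path, null: bool = False) -> dict:
    """Generate a small panel, run the full pipeline, summarize recovery.

    Five tissues, 300 genes, 30 samples/group; one 20-gene module whose
    loading collapses with age and whose genes are also shifted in mean,
    plus 20 pure-DE genes. The "Many" boundary is lowered to 4 of 5
    tissues so the cross-tissue categories are populated at panel scale.
    With ``null`` the generator's global-null variant is used and every
    downstream discovery is a false positive.
    """
    out_dir = Path(out_dir)
    cohort = dataclasses.replace(DEMO_COHORT, seed=derive_seed(seed, "cohort"))
    if null:
        cohort = cohort.null()
    run_cfg = dataclasses.replace(DEMO_RUN, seed=seed)
    data_dir = out_dir / "data"
    simulate_panel(cohort, data_dir, write_counts=False)
    manifest = run_all(run_cfg, data_dir, out_dir / "results")
    summary = summarize_recovery(cohort, run_cfg, data_dir, out_dir / "results")
    (out_dir / "recovery.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def summarize_recovery(cohort: CohortConfig, run_cfg: RunConfig,
                       data_dir: str | Path, results_dir: str | Path) -> dict:
    """Compare pipeline output with the generator's planted truth."""
    data_dir, results_dir = Path(data_dir), Path(results_dir)
    meta = read_metadata(data_dir / "metadata.tsv")
    tissues = meta.tissues()

    truth = pd.read_csv(data_dir / f"{tissues[0]}.truth.tsv", sep="\t")
    planted_de = set(truth.loc[truth["is_de"] & (truth["de_sign"] != 0),
                               "gene_id"])
    planted_conn = set(truth.loc[truth["connectivity_delta"], "gene_id"])

    de_sens, de_fdr, dn_recall = [], [], []
    for tissue in tissues:
        de = diffexpr.read_de_table(results_dir / f"{tissue}.de.tsv")
        called = diffexpr.significant_genes(de)
        if planted_de:
            de_sens.append(len(called & planted_de) / len(planted_de))
        false = called - planted_de
        de_fdr.append(len(false) / max(len(called), 1))
        dn = dysregulation.read_dn_table(results_dir / f"{tissue}.dn.tsv")
        dns = dysregulation.dn_genes(dn)
        if planted_conn:
            dn_recall.append(len(dns & planted_conn) / len(planted_conn))

    atlas = pd.read_csv(results_dir / "atlas.tsv", sep="\t")
    core = set(atlas.loc[atlas["in_core_set"], "gene_id"])
    summary = {
        "n_tissues": len(tissues),
        "planted_de_genes": len(planted_de),
        "planted_connectivity_genes": len(planted_conn),
        "de_sensitivity": float(pd.Series(de_sens).mean()) if de_sens else None,
        "de_empirical_fdr": float(pd.Series(de_fdr).mean()),
        "dn_recall": float(pd.Series(dn_recall).mean()) if dn_recall else None,
        "core_set_size": len(core),
        "core_set_recall_of_planted": (
            len(core & planted_conn) / len(planted_conn) if planted_conn else None),
    }
    overall = results_dir / "overall.report.json"
    if overall.exists():
        rep = json.loads(overall.read_text())
        summary["overall_auc"] = rep["auc"]
        summary["overall_oob_score"] = rep["oob_score"]
    composite = results_dir / "composite.report.json"
    if composite.exists():
        rep = json.loads(composite.read_text())
        summary["composite_auc"] = rep["auc"]
    return summary
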