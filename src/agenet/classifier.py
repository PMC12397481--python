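"""Random-forest age-group classification and biomarker ranking.

The overall model is trained on the core biomarker set: features are
log2(TPM + 1) per gene, samples are labelled young/aging, and a
1000-tree bootstrap forest with out-of-bag scoring is fitted on a
stratified 70/30 train/test split. AUC and accuracy are reported on the
held-out 30% only; the OOB score is reported alongside. Feature
importances (mean impurity decrease, normalized to sum to 1) rank the
genes; per-tissue models refit the same feature list within each tissue,
and the composite predictor pools several tissues' samples over the
union of their per-tissue top features, z-scoring expression within each
tissue first so tissue identity cannot leak into the pooled model as a
proxy for age group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .io import AGING, GROUPS, RunConfig, ValidationError

logger = logging.getLogger("agenet")


@dataclass
class ClassifierReport:
    """Held-out metrics, OOB score and feature ranking of one fitted forest."""

    auc: float
    accuracy: float
    oob_score: float
    feature_importances: pd.Series = field(repr=False)  # sums to 1
    top_features: list[str] = field(default_factory=list)
    n_train: int = 0
    n_test: int = 0
    seed: int = 0
    roc: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    params: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "oob_score": self.oob_score,
            "n_train": self.n_train, "n_test": self.n_test,
            "seed": self.seed,
            "feature_importances": self.feature_importances.to_dict(),
            "top_features": list(self.top_features),
            "params": self.params,
        }


def _check_features(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    if len(features) != len(labels):
        raise ValidationError("features and labels differ in length")
    labels = pd.Series(np.asarray(labels, dtype=object), index=features.index)
    bad = sorted(set(labels) - set(GROUPS))
    if bad:
        raise ValidationError(f"labels must be in {GROUPS}, got {bad}")
    if labels.nunique() < 2:
        raise ValidationError("single-class input: cannot fit a classifier")
    return labels


def fit_rf(features: pd.DataFrame, labels, config: RunConfig,
           seed: int | None = None) -> ClassifierReport:
    """Fit the forest on a stratified train/test split of samples x genes.

    ``features`` rows are samples, columns genes, values log2(TPM + 1)
    (or any monotone transform — the forest is scale-free per feature).
    Deterministic given the seed: the split and the forest share it.
    """
    labels = _check_features(features, labels)
    seed = config.seed if seed is None else seed
    y = (labels == AGING).astype(int).to_numpy()
    X = features.to_numpy(dtype=float)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.rf_train_fraction, stratify=y,
        random_state=seed)
    if min(np.bincount(y_tr, minlength=2)) < 2 or \
            min(np.bincount(y_te, minlength=2)) < 2:
        raise ValidationError("need >= 2 samples per class in train and test")

    rf = RandomForestClassifier(
        n_estimators=config.rf_trees, bootstrap=True, oob_score=True,
        random_state=seed, n_jobs=1)
    rf.fit(X_tr, y_tr)

    prob = rf.predict_proba(X_te)[:, 1]
    fpr, tpr, thr = roc_curve(y_te, prob)
    imp = pd.Series(rf.feature_importances_, index=features.columns)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = sorted(features.columns, key=lambda g: (-imp[g], g))
    return ClassifierReport(
        auc=float(roc_auc_score(y_te, prob)),
        accuracy=float(accuracy_score(y_te, rf.predict(X_te))),
        oob_score=float(rf.oob_score_),
        feature_importances=imp,
        top_features=order,
        n_train=len(y_tr), n_test=len(y_te), seed=seed,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        params={k: v for k, v in rf.get_params().items()
                if k in ("n_estimators", "max_depth", "max_features",
                         "min_samples_split", "min_samples_leaf",
                         "criterion", "bootstrap", "oob_score")},
    )


def rank_features(report: ClassifierReport, k: int) -> list[str]:
    """Top-k genes by importance (descending, lexical tie-break)."""
    n = len(report.top_features)
    if k > n:
        logger.warning("requested top %d of %d features; returning all", k, n)
        k = n
    return list(report.top_features[:k])


def feature_table(tpm_data: pd.DataFrame, genes: list[str],
                  warn_missing: bool = True) -> pd.DataFrame:
    """Samples x genes log2(TPM + 1) feature matrix; absent genes are
    filled with zero expression (logged)."""
    missing = [g for g in genes if g not in tpm_data.index]
    if missing and warn_missing:
        logger.warning("%d feature gene(s) absent from matrix, imputed as "
                       "unexpressed: %s", len(missing), missing[:5])
    present = [g for g in genes if g in tpm_data.index]
    feats = np.log2(tpm_data.loc[present].to_numpy(dtype=float).T + 1.0)
    out = pd.DataFrame(feats, index=tpm_data.columns, columns=present)
    for g in missing:
        out[g] = 0.0
    return out[list(genes)]


def per_tissue_eval(top_genes: list[str],
                    tissue_data: dict[str, tuple[pd.DataFrame, pd.Series]],
                    config: RunConfig,
                    seed: int | None = None) -> pd.Series:
    """Refit + evaluate one forest per tissue on a shared feature list.

    ``tissue_data`` maps tissue -> (TPM genes x samples, labels per
    sample). Tissues that cannot support a stratified fit are skipped
    with a log entry and omitted from the returned AUC table.
    """
    aucs = {}
    for tissue in sorted(tissue_data):
        tpm_data, labels = tissue_data[tissue]
        try:
            feats = feature_table(tpm_data, top_genes)
            report = fit_rf(feats, labels, config, seed=seed)
        except ValidationError as exc:
            logger.warning("tissue %s skipped in per-tissue eval: %s", tissue, exc)
            continue
        aucs[tissue] = report.auc
    return pd.Series(aucs, name="auc")


def composite_predictor(per_tissue_top: dict[str, list[str]],
                        tissue_data: dict[str, tuple[pd.DataFrame, pd.Series]],
                        config: RunConfig,
                        seed: int | None = None) -> ClassifierReport:
    """Pool several tissues over the union of their top feature lists.

    Per-tissue feature matrices are z-scored within tissue (unless
    ``config.rf_zscore_composite`` is off) before pooling, then a single
    forest is fitted and evaluated exactly as :func:`fit_rf`.
    """
    if len(per_tissue_top) < 2:
        raise ValidationError("composite predictor needs >= 2 tissues")
    union: list[str] = sorted(set().union(*per_tissue_top.values()))
    if not union:
        raise ValidationError("empty feature union")
    blocks, label_blocks = [], []
    for tissue in sorted(per_tissue_top):
        if tissue not in tissue_data:
            raise ValidationError(f"no expression data for tissue {tissue!r}")
        tpm_data, labels = tissue_data[tissue]
        feats = feature_table(tpm_data, union)
        if config.rf_zscore_composite:
            sd = feats.std(axis=0, ddof=0).replace(0.0, 1.0)
            feats = (feats - feats.mean(axis=0)) / sd
        blocks.append(feats)
        label_blocks.append(pd.Series(np.asarray(labels, dtype=object),
                                      index=feats.index))
    pooled = pd.concat(blocks, axis=0)
    pooled_labels = pd.concat(label_blocks, axis=0)
    return fit_rf(pooled, pooled_labels, config, seed=seed)


def write_report(report: ClassifierReport, out_dir: str | Path,
                 prefix: str = "classifier") -> list[Path]:
    """report.json + roc.tsv + importance.tsv under ``out_dir``."""
    import json
    out_dir = Path(out_dir)
    paths = []
    p = out_dir / f"{prefix}.report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    paths.append(p)
    p = out_dir / f"{prefix}.roc.tsv"
    report.roc.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out_dir / f"{prefix}.importance.tsv"
    report.feature_importances.rename("importance").rename_axis("gene_id") \
        .reset_index().to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths
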