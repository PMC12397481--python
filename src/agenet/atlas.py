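"""Cross-tissue aggregation of DEG and DN status.

For every gene the atlas counts the tissues where it is a significant DEG
and the tissues where it is a DN, then maps each count to a
tissue-distribution category:

* ``none``   — 0 tissues
* ``single`` — exactly 1 tissue (tissue-restricted signal)
* ``some``   — 2 up to many_min_tissues - 1 tissues (default 2-13)
* ``many``   — many_min_tissues or more (default >= 14; systemic signal)

The *core biomarker set* is the intersection of the "DEG in Many" and
"DN in Many" gene sets — genes that both change expression and change
co-expression connectivity across much of the tissue panel.

Category percentages are computed over the ever-detected universe: genes
that were tested in at least one tissue. Genes never tested are excluded
from denominators (they carry no evidence either way).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .io import RunConfig, ValidationError

CATEGORIES = ("none", "single", "some", "many")

ATLAS_COLUMNS = ["gene_id", "n_tissues_deg", "deg_category",
                 "n_tissues_dn", "dn_category", "in_core_set"]


def count_tissues(per_tissue_sets: dict[str, set[str]],
                  universe: set[str] | None = None) -> dict[str, int]:
    """Per-gene count of tissues whose set contains the gene.

    Genes present in no set are reported with count 0 only when a
    ``universe`` is supplied.
    """
    counts: dict[str, int] = dict.fromkeys(universe or (), 0)
    for genes in per_tissue_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def categorize(count: int, config: RunConfig) -> str:
    """Map a tissue count to none/single/some/many (total on count >= 0)."""
    if count < 0:
        raise ValidationError("tissue count must be >= 0")
    if count == 0:
        return "none"
    if count < config.some_min_tissues:
        return "single"
    if count < config.many_min_tissues:
        return "some"
    return "many"


def build_atlas(deg_sets: dict[str, set[str]], dn_sets: dict[str, set[str]],
                config: RunConfig,
                universe: set[str] | None = None) -> pd.DataFrame:
    """Assemble the per-gene cross-tissue atlas table.

    ``universe`` defaults to every gene appearing in any DEG or DN set
    (callers aggregating real runs should pass the union of per-tissue
    tested genes so never-significant genes appear with count 0).
    """
    if set(deg_sets) != set(dn_sets):
        raise ValidationError(
            "DEG and DN sets must cover the same tissue panel: "
            f"{sorted(set(deg_sets) ^ set(dn_sets))}")
    if universe is None:
        universe = set()
        for s in (*deg_sets.values(), *dn_sets.values()):
            universe |= s
    deg_counts = count_tissues(deg_sets, universe)
    dn_counts = count_tissues(dn_sets, universe)
    genes = sorted(universe)
    n_deg = [deg_counts[g] for g in genes]
    n_dn = [dn_counts[g] for g in genes]
    deg_cat = [categorize(c, config) for c in n_deg]
    dn_cat = [categorize(c, config) for c in n_dn]
    return pd.DataFrame({
        "gene_id": genes,
        "n_tissues_deg": n_deg,
        "deg_category": deg_cat,
        "n_tissues_dn": n_dn,
        "dn_category": dn_cat,
        "in_core_set": [dc == "many" and nc == "many"
                        for dc, nc in zip(deg_cat, dn_cat)],
    })


def core_biomarker_set(atlas: pd.DataFrame) -> list[str]:
    """Genes that are simultaneously DEG-in-Many and DN-in-Many, sorted."""
    return sorted(atlas.loc[atlas["in_core_set"], "gene_id"])


def atlas_summary(atlas: pd.DataFrame) -> dict:
    """Per-category counts and percentages over the ever-detected universe."""
    n = len(atlas)
    out: dict = {"universe_size": n, "core_set_size": int(atlas["in_core_set"].sum())}
    for kind in ("deg", "dn"):
        col = atlas[f"{kind}_category"]
        counts = {c: int((col == c).sum()) for c in CATEGORIES}
        out[f"{kind}_counts"] = counts
        out[f"{kind}_percent"] = {c: (100.0 * v / n if n else 0.0)
                                  for c, v in counts.items()}
    return out


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def write_summary(atlas: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(atlas_summary(atlas), indent=2) + "\n")
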