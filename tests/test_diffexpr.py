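import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from agenet import (ExpressionMatrix, RunConfig, SampleMetadata,
                    ValidationError, bh_adjust, builtin_de,
                    ingest_external_de, significant_genes)


def brute_force_bh(p):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                   atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 200))
            np.testing.assert_allclose(
                bh_adjust(p),
                multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def _two_group(young_cols, aging_cols):
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": young_cols + aging_cols,
        "group": ["young"] * len(young_cols) + ["aging"] * len(aging_cols),
        "tissue": "t0",
        "batch": "b1",
    }))
    return meta


class TestBuiltinDe:
    def test_identical_groups_yield_null_table(self):
        data = pd.DataFrame(
            [[8.0, 9.0, 8.0, 9.0], [20.0, 30.0, 20.0, 30.0]],
            index=["g1", "g2"], columns=["y1", "y2", "a1", "a2"])
        de = builtin_de(ExpressionMatrix(data, "tpm"),
                        _two_group(["y1", "y2"], ["a1", "a2"]), RunConfig())
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)
        assert not de["significant"].any()

    def test_matches_closed_form_welch_t(self):
        # one test gene with log2(TPM+1) exactly (1..5) young, (6..10) aging
        # plus two flat genes so sample normalization is a no-op
        y_vals = np.array([1.0, 2, 3, 4, 5])
        a_vals = np.array([6.0, 7, 8, 9, 10])
        tpm = np.vstack([
            2.0 ** np.concatenate([y_vals, a_vals]) - 1.0,
            np.full(10, 100.0),
            np.full(10, 50.0),
        ])
        cols = [f"y{i}" for i in range(5)] + [f"a{i}" for i in range(5)]
        mat = ExpressionMatrix(pd.DataFrame(
            tpm, index=["g_test", "flat1", "flat2"], columns=cols), "tpm")
        de = builtin_de(mat, _two_group(cols[:5], cols[5:]), RunConfig())
        row = de.set_index("gene_id").loc["g_test"]
        assert row["log2fc"] == pytest.approx(5.0, abs=1e-9)
        # textbook Welch: t = diff / sqrt(s1^2/n1 + s2^2/n2), Welch df
        s2 = np.var(y_vals, ddof=1)
        se = math.sqrt(s2 / 5 + s2 / 5)
        t_stat = 5.0 / se
        df = (s2 / 5 + s2 / 5) ** 2 / ((s2 / 5) ** 2 / 4 + (s2 / 5) ** 2 / 4)
        from scipy import stats as sps
        p_oracle = 2 * sps.t.sf(abs(t_stat), df)
        assert row["p_value"] == pytest.approx(p_oracle, rel=1e-9)
        assert row["direction"] == "up"

    def test_zero_variance_gene_flagged_with_p_one(self):
        # two constant genes anchor the per-sample normalization at zero
        data = pd.DataFrame(
            [[7.0, 7.0, 15.0, 15.0], [100.0] * 4, [50.0] * 4],
            index=["flat_shift", "c1", "c2"], columns=["y1", "y2", "a1", "a2"])
        de = builtin_de(ExpressionMatrix(data, "tpm"),
                        _two_group(["y1", "y2"], ["a1", "a2"]), RunConfig())
        row = de.set_index("gene_id").loc["flat_shift"]
        assert row["zero_variance"]
        assert row["p_value"] == 1.0
        assert row["log2fc"] > 0  # still computed from the means

    def test_single_sample_group_rejected(self, tiny_tpm):
        meta = _two_group(["s1"], ["s2", "s3", "s4"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            builtin_de(tiny_tpm, meta, RunConfig())

    def test_gene_order_invariance_and_direction_partition(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.lognormal(3, 1, size=(40, 20)),
            index=[f"g{i:02d}" for i in range(40)],
            columns=[f"s{i}" for i in range(20)])
        meta = _two_group([f"s{i}" for i in range(10)],
                          [f"s{i}" for i in range(10, 20)])
        de1 = builtin_de(ExpressionMatrix(data, "tpm"), meta, RunConfig())
        shuffled = data.sample(frac=1.0, random_state=1)
        de2 = builtin_de(ExpressionMatrix(shuffled, "tpm"), meta, RunConfig())
        pd.testing.assert_frame_equal(de1, de2)
        assert set(de1["direction"]) <= {"up", "down"}
        assert len(de1) == 40

    def test_null_cohort_significant_fraction_controlled(self):
        # FDR control: mean significant fraction under the global null
        # stays near the nominal level (slack for Monte-Carlo noise)
        from agenet import generate_tissue
        from conftest import null_cohort_config
        fracs = []
        for rep in range(50):
            cfg = null_cohort_config(n_genes=200, per_group=30, seed=500 + rep)
            _, tpm, meta, _ = generate_tissue(cfg, 0)
            de = builtin_de(tpm, meta, RunConfig())
            fracs.append(de["significant"].mean())
        assert np.mean(fracs) <= 0.05 * 1.5


class TestIngestExternal:
    def _write(self, tmp_path, rows):
        path = tmp_path / "external.de.tsv"
        df = pd.DataFrame(rows, columns=["gene", "log2FoldChange", "pvalue",
                                         "padj"])
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_rule_application(self, tmp_path):
        path = self._write(tmp_path, [("geneA", 1.5, 1e-6, 1e-4),
                                      ("geneB", -0.01, 0.2, 0.6)])
        table = ingest_external_de(path, RunConfig()).set_index("gene_id")
        assert table.loc["geneA", "direction"] == "up"
        assert bool(table.loc["geneA", "significant"])
        # tiny negative effect is still "down": no magnitude cutoff
        assert table.loc["geneB", "direction"] == "down"
        assert not table.loc["geneB", "significant"]

    def test_missing_padj_treated_as_not_significant(self, tmp_path):
        path = self._write(tmp_path, [("geneC", 2.0, 1e-8, np.nan)])
        table = ingest_external_de(path, RunConfig())
        assert not table["significant"].any()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene": ["g"], "lfc": [1.0]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="missing columns"):
            ingest_external_de(path, RunConfig())


def test_significant_genes_ignores_direction(tmp_path):
    table = pd.DataFrame({
        "gene_id": ["a", "b", "c"],
        "log2fc": [1.0, -2.0, 0.5],
        "significant": [True, True, False],
    })
    assert significant_genes(table) == {"a", "b"}
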