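import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from agenet import (CoexpressionNetwork, ExpressionMatrix, RunConfig,
                    ValidationError, build_network, degree_centrality,
                    filter_genes, generate_tissue, spearman_rho)
from agenet.network import _t_approx_p


def closed_form_rho(x, y):
    """Tie-free closed form: 1 - 6 * sum(d^2) / (n * (n^2 - 1))."""
    d = stats.rankdata(x) - stats.rankdata(y)
    n = len(x)
    return 1.0 - 6.0 * float(d @ d) / (n * (n ** 2 - 1))


class TestSpearmanRho:
    def test_textbook_example(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_monotone_transform_invariance(self):
        x = np.array([0.3, 1.7, 2.1, 5.5, 9.0, 12.0])
        rho, p = spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_ties_match_midrank_pearson_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(5, 30)
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_p_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(5, 40)
            x, y = rng.normal(size=(2, n))
            rho, p = spearman_rho(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_tie_free_closed_form_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        x, y = rng.normal(size=(2, n))
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(closed_form_rho(x, y), abs=1e-12)


class TestFilterGenes:
    def _tpm(self, rows, n_samples=3):
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                          columns=[f"s{i}" for i in range(n_samples)])
        return ExpressionMatrix(df, "tpm")

    def test_strictly_above_threshold_retained(self):
        tpm = self._tpm([[6.0, 6.0, 6.0], [5.0, 5.0, 5.0]])
        kept = filter_genes(tpm, ["s0", "s1", "s2"], threshold=5.0)
        assert kept == ["g0"]  # (5,5,5) dropped: strict >

    def test_median_rule_drops_outlier_driven_gene(self):
        tpm = self._tpm([[0.0, 0.0, 100.0]])
        assert filter_genes(tpm, ["s0", "s1", "s2"]) == []

    @pytest.mark.parametrize("rule, expected", [
        ("median", ["g0"]),   # median 8 > 5
        ("mean", ["g0"]),     # mean 36 > 5
        ("all", []),          # min 0.5 fails
    ])
    def test_alternative_rules(self, rule, expected):
        tpm = self._tpm([[0.5, 8.0, 100.0]])
        assert filter_genes(tpm, ["s0", "s1", "s2"], rule=rule) == expected


def _monotone_tpm(n_samples=20):
    """Three strictly co-monotone genes, all above the filter."""
    base = np.linspace(10, 50, n_samples)
    df = pd.DataFrame(
        [base, base ** 1.5, 2 * base + 3],
        index=["gA", "gB", "gC"],
        columns=[f"s{i}" for i in range(n_samples)])
    return ExpressionMatrix(df, "tpm")


class TestBuildNetwork:
    def test_perfectly_comonotone_genes_form_complete_graph(self):
        tpm = _monotone_tpm()
        net = build_network(tpm, tpm.sample_ids, RunConfig(), "t", "young")
        assert len(net.edges) == 3
        np.testing.assert_allclose(net.edges["rho"], 1.0)
        assert (net.edges["q"] < 1e-4).all()
        assert net.degree.tolist() == [2, 2, 2]
        assert net.n_pairs_tested == 3

    def test_order_invariance(self, module_cohort):
        _, (_, tpm, meta, _) = module_cohort
        samples = meta.samples_in_group("young")
        net1 = build_network(tpm, samples, RunConfig(), "t", "young")
        shuffled = ExpressionMatrix(
            tpm.data.sample(frac=1.0, random_state=4)[samples[::-1]], "tpm")
        net2 = build_network(shuffled, list(reversed(samples)), RunConfig(),
                             "t", "young")
        pd.testing.assert_frame_equal(net1.edges, net2.edges)
        pd.testing.assert_series_equal(net1.degree, net2.degree)

    def test_fdr_monotonicity(self, module_cohort):
        _, (_, tpm, meta, _) = module_cohort
        samples = meta.samples_in_group("young")
        loose = build_network(tpm, samples, RunConfig(edge_fdr=0.05), "t", "y")
        tight = build_network(tpm, samples, RunConfig(edge_fdr=0.005), "t", "y")
        loose_pairs = set(map(tuple, loose.edges[["gene_a", "gene_b"]].values))
        tight_pairs = set(map(tuple, tight.edges[["gene_a", "gene_b"]].values))
        assert tight_pairs <= loose_pairs
        assert (tight.degree.reindex(loose.degree.index, fill_value=0)
                <= loose.degree).all()

    def test_module_genes_densely_connected_in_high_loading_group(self):
        # 20-gene module at loading 0.9, n=60: every module gene keeps
        # within-module degree >= 10 in the young network, across seeds
        from agenet import CohortConfig
        for seed in range(5):
            cfg = CohortConfig(n_genes=120, n_tissues=1, n_young=60,
                               n_aging=2, n_de_genes=0, de_log2fc=0.0,
                               module_sizes=(20,), loading_young=(0.9,),
                               loading_aging=(0.0,), seed=seed)
            _, tpm, meta, truth = generate_tissue(cfg, 0)
            net = build_network(tpm, meta.samples_in_group("young"),
                                RunConfig(), "t", "young")
            module = sorted(truth.module_assignments)
            within = net.edges[net.edges["gene_a"].isin(module)
                               & net.edges["gene_b"].isin(module)]
            deg = pd.Series(0, index=module, dtype=int)
            for col in ("gene_a", "gene_b"):
                deg = deg.add(within[col].value_counts(), fill_value=0)
            assert int(deg.min()) >= 10

    def test_handshake_identity(self, module_cohort):
        _, (_, tpm, meta, _) = module_cohort
        net = build_network(tpm, meta.samples_in_group("young"), RunConfig(),
                            "t", "young")
        assert net.degree.sum() == 2 * net.n_positive_edges

    def test_constant_gene_pairs_skipped_not_fatal(self):
        base = np.linspace(10, 50, 12)
        df = pd.DataFrame([base, base + 1, np.full(12, 30.0)],
                          index=["gA", "gB", "gConst"],
                          columns=[f"s{i}" for i in range(12)])
        net = build_network(ExpressionMatrix(df, "tpm"),
                            list(df.columns), RunConfig(), "t", "y")
        assert net.n_pairs_skipped == 2
        assert net.n_pairs_tested == 1
        assert "gConst" in net.nodes


class TestDegreeCentrality:
    def _net(self):
        edges = pd.DataFrame({
            "gene_a": ["A", "A", "B"],
            "gene_b": ["B", "C", "C"],
            "rho": [0.9, 0.8, -0.7],
            "p": [1e-6, 1e-5, 1e-4],
            "q": [1e-4, 1e-3, 1e-2],
        })
        deg = pd.Series({"A": 2, "B": 1, "C": 1})
        neg = pd.Series({"A": 0, "B": 1, "C": 1})
        return CoexpressionNetwork("t", "young", ["A", "B", "C"], edges,
                                   deg, neg, 3, 0)

    def test_positive_only_hand_count(self):
        deg = degree_centrality(self._net())
        assert deg.to_dict() == {"A": 2, "B": 1, "C": 1}

    def test_including_negative_edges(self):
        deg = degree_centrality(self._net(), positive_only=False)
        assert deg.to_dict() == {"A": 2, "B": 2, "C": 2}

    def test_empty_network_all_zero(self):
        net = CoexpressionNetwork(
            "t", "young", ["A", "B"],
            pd.DataFrame(columns=["gene_a", "gene_b", "rho", "p", "q"]),
            pd.Series(0, index=["A", "B"]), pd.Series(0, index=["A", "B"]))
        assert degree_centrality(net).sum() == 0


def test_t_approximation_matches_scipy_formula():
    rng = np.random.default_rng(9)
    rho = rng.uniform(-0.99, 0.99, size=100)
    for n in (10, 30, 80):
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        expected = 2 * stats.t.sf(np.abs(t), n - 2)
        np.testing.assert_allclose(_t_approx_p(rho, n), expected, rtol=1e-12)
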