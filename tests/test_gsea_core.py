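import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import bruteforce_enrichment_score
from uprhd.gsea_core import (
    EnrichmentResult,
    RankedList,
    Thresholds,
    UndefinedNESError,
    classify_regulation,
    enrichment_score,
    leading_edge,
    normalize_and_test,
    permutation_null,
    rank_genes,
)
from uprhd.io_gene_sets import ExpressionDataset
from uprhd.synthetic_data import simulate_expression


def _ranked(scores, genes=None):
    genes = genes or [f"G{i+1}" for i in range(len(scores))]
    return RankedList(genes=genes, scores=np.asarray(scores, dtype=float), metric="test")


def _dataset(case_rows, ctrl_rows, genes):
    values = np.hstack([np.asarray(case_rows, float), np.asarray(ctrl_rows, float)])
    n_case = np.asarray(case_rows).shape[1]
    n_ctrl = np.asarray(ctrl_rows).shape[1]
    return ExpressionDataset(
        genes, [f"s{i}" for i in range(n_case + n_ctrl)], values,
        ["case"] * n_case + ["control"] * n_ctrl)


class TestRankGenes:
    def test_signal2noise_with_variance_floor(self):
        # (4-2)/(0.2*4 + 0.2*2) = 2/1.2, both SDs floored at 0.2*|mean|
        ds = _dataset([[4, 4, 4], [1, 1, 1]], [[2, 2, 2], [1, 1, 1]], ["A", "B"])
        ranked = rank_genes(ds, metric="signal2noise")
        assert ranked.genes[0] == "A"
        assert ranked.scores[0] == pytest.approx(2 / 1.2)

    def test_equal_means_score_zero(self):
        ds = _dataset([[3, 3, 3]], [[3, 3, 3]], ["A"])
        assert rank_genes(ds).scores[0] == 0.0

    def test_ties_broken_lexicographically(self):
        ds = _dataset([[5, 5, 5], [5, 5, 5]], [[1, 1, 1], [1, 1, 1]], ["ZZZ", "AAA"])
        assert rank_genes(ds).genes == ["AAA", "ZZZ"]

    def test_small_groups_fall_back_to_log2fc(self):
        ds = _dataset([[4, 4], [1, 1]], [[2, 2], [1, 1]], ["A", "B"])
        with pytest.warns(UserWarning, match="log2fc"):
            ranked = rank_genes(ds, metric="signal2noise")
        assert ranked.metric == "log2fc"
        assert ranked.scores[0] == pytest.approx(2.0)


class TestEnrichmentScore:
    def test_full_set_scores_exactly_one(self):
        ranked = _ranked([5.0, 3.0, 1.0])
        es, peak, _ = enrichment_score(ranked, set(ranked.genes), min_set_size=1)
        assert es == 1.0

    def test_hand_example_top_and_bottom_gene(self):
        ranked = _ranked(np.arange(10, 0, -1))
        es, peak, _ = enrichment_score(ranked, {"G1", "G10"}, min_set_size=1)
        assert es == pytest.approx(10 / 11)
        assert peak == 0

    def test_bottom_concentrated_set_negative(self):
        ranked = _ranked(np.arange(10, 0, -1))
        es, _, _ = enrichment_score(ranked, {"G9", "G10"}, min_set_size=1)
        assert es < 0

    def test_missing_set_and_min_size(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="not represented"):
            enrichment_score(ranked, {"NOPE"}, min_set_size=1)
        with pytest.raises(ValueError, match="min_set_size"):
            enrichment_score(ranked, {"G1"}, min_set_size=5)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(10, 120))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"G{i}" for i in range(n)]
            members = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            ranked = _ranked(scores, genes)
            es, peak, _ = enrichment_score(ranked, members, min_set_size=1)
            flags = [g in members for g in genes]
            es_o, peak_o = bruteforce_enrichment_score(scores, flags)
            assert es == pytest.approx(es_o)
            assert peak == peak_o

    @given(st.integers(0, 2**31 - 1))
    def test_es_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"G{i}" for i in range(n)]
        members = set(rng.choice(genes, size=int(rng.integers(1, n + 1)), replace=False))
        es, _, _ = enrichment_score(_ranked(scores, genes), members, min_set_size=1)
        assert -1.0 <= es <= 1.0

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=40))[::-1]
        genes = [f"G{i}" for i in range(40)]
        members = set(rng.choice(genes, size=8, replace=False))
        es_fwd, _, _ = enrichment_score(_ranked(scores, genes), members, min_set_size=1)
        es_rev, _, _ = enrichment_score(_ranked(-scores[::-1], genes[::-1]), members, min_set_size=1)
        assert es_rev == pytest.approx(-es_fwd)


class TestLeadingEdge:
    def test_positive_es_takes_members_before_peak(self):
        ranked = _ranked(np.arange(10, 0, -1))
        es, peak, _ = enrichment_score(ranked, {"G1", "G10"}, min_set_size=1)
        assert leading_edge(ranked, {"G1", "G10"}, es, peak) == ["G1"]

    def test_set_entirely_above_peak_is_whole_set(self):
        ranked = _ranked(np.arange(10, 0, -1))
        members = {"G1", "G2", "G3"}
        es, peak, _ = enrichment_score(ranked, members, min_set_size=1)
        assert set(leading_edge(ranked, members, es, peak)) == members

    def test_mirrored_ranking_gives_same_leading_edge(self):
        rng = np.random.default_rng(11)
        scores = np.sort(rng.normal(size=30))[::-1]
        genes = [f"G{i}" for i in range(30)]
        members = set(rng.choice(genes[:6], size=3, replace=False))
        ranked = _ranked(scores, genes)
        es, peak, _ = enrichment_score(ranked, members, min_set_size=1)
        mirrored = _ranked(-scores[::-1], genes[::-1])
        es_m, peak_m, _ = enrichment_score(mirrored, members, min_set_size=1)
        assert set(leading_edge(ranked, members, es, peak)) == set(
            leading_edge(mirrored, members, es_m, peak_m))

    def test_zero_es_rejected(self):
        with pytest.raises(ValueError):
            leading_edge(_ranked([1.0]), {"G1"}, 0.0, 0)


class TestPermutationNull:
    def test_same_seed_identical(self):
        ds, truth = simulate_expression(n_genes=60, n_case=4, n_control=4, planted_set_size=10, seed=2)
        a = permutation_null(ds, truth.planted_set, mode="gene_set", n_perm=50, seed=9)
        b = permutation_null(ds, truth.planted_set, mode="gene_set", n_perm=50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_gene_set_mode_full_set_degenerate(self):
        ds, _ = simulate_expression(n_genes=20, n_case=4, n_control=4, planted_set_size=0, seed=2)
        null = permutation_null(ds, set(ds.gene_ids), mode="gene_set", n_perm=20, seed=0)
        np.testing.assert_allclose(null, 1.0)

    def test_n_perm_bounds(self):
        ds, truth = simulate_expression(n_genes=30, n_case=4, n_control=4, planted_set_size=5, seed=2)
        with pytest.raises(ValueError):
            permutation_null(ds, truth.planted_set, n_perm=5)
        with pytest.warns(UserWarning, match="small"):
            permutation_null(ds, truth.planted_set, n_perm=20, seed=1)

    def test_phenotype_mode_reproducible(self):
        ds, truth = simulate_expression(n_genes=40, n_case=8, n_control=8, planted_set_size=8, seed=3)
        a = permutation_null(ds, truth.planted_set, mode="phenotype", n_perm=30, seed=4)
        b = permutation_null(ds, truth.planted_set, mode="phenotype", n_perm=30, seed=4)
        np.testing.assert_array_equal(a, b)


class TestNormalizeAndTest:
    def test_es_at_null_mean_gives_nes_one(self):
        null = np.array([0.2, 0.4, 0.6, -0.3, -0.5])
        nes, _, _ = normalize_and_test(0.4, null)
        assert nes == pytest.approx(1.0)

    def test_extreme_es_gets_add_one_p(self):
        null = np.abs(np.random.default_rng(0).normal(size=999)) * 0.1
        nes, p, fdr = normalize_and_test(0.99, null)
        assert p == pytest.approx(1 / 1000)
        assert 0.0 <= fdr <= 1.0

    def test_hand_computed_fdr_on_ten_value_null(self):
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        # all null ES <= observed: tail fraction 1/10 at the observed value
        nes, p, fdr = normalize_and_test(1.0, null)
        assert fdr == pytest.approx(0.1)
        assert p == pytest.approx(2 / 11)

    def test_one_sided_null_flagged(self):
        with pytest.raises(UndefinedNESError):
            normalize_and_test(-0.5, np.array([0.1, 0.2, 0.3]))

    def test_zero_es_neutral(self):
        assert normalize_and_test(0.0, np.array([0.5, -0.5])) == (0.0, 1.0, 1.0)


class TestClassifyRegulation:
    @pytest.mark.parametrize("nes,fdr,expected", [
        (1.5, 0.01, "up"),
        (1.5, 0.2, "ns"),
        (-1.6, 0.01, "down"),
        (1.39, 0.01, "ns"),
        (-1.2, 0.001, "ns"),
    ])
    def test_threshold_rule(self, nes, fdr, expected):
        res = EnrichmentResult("s", 10, 0.5, 0, nes=nes, p_perm=0.01, fdr=fdr)
        assert classify_regulation(res, Thresholds()) == expected

    def test_threshold_invariant(self):
        with pytest.raises(ValueError):
            Thresholds(nes_up_min=-1.0)
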