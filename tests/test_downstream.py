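"""Downstream analyses: baselines, PR sweeps, GSEA, ORA, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cogs.downstream import (
    _es_running,
    cluster_expression,
    compare_sets,
    gsea_preranked,
    nearest_exon_assign,
    ora_hypergeometric,
    precision_recall,
    prioritise,
    top_expression_filter,
)
from cogs.simulate import simulate_expression
from cogs.types import CogsError, GeneModelSet, InvalidConfigError


def scores_df(pairs):
    return pd.DataFrame([{"gene_id": g, "score": s} for g, s in pairs])


class TestPrioritise:
    def test_threshold_is_strict(self):
        out = prioritise(scores_df([("A", 0.31), ("B", 0.30), ("C", 0.29)]), 0.3)
        assert out == {"A"}

    def test_zero_threshold_keeps_positive_scores(self):
        out = prioritise(scores_df([("A", 0.1), ("B", 0.0)]), 0.0)
        assert out == {"A"}

    def test_threshold_one_empty(self):
        assert prioritise(scores_df([("A", 1.0)]), 1.0) == set()


class TestNearestExon:
    @pytest.fixture
    def genes(self):
        meta = pd.DataFrame(
            {"gene_id": ["A", "B"], "name": ["A", "B"], "chrom": ["1", "1"],
             "strand": ["+", "+"], "biotype": ["protein_coding"] * 2}
        )
        tss = pd.DataFrame({"gene_id": ["A", "B"], "chrom": ["1", "1"], "pos": [1000, 5000]})
        exons = pd.DataFrame(
            {"gene_id": ["A", "B"], "chrom": ["1", "1"], "start": [1000, 5001], "end": [1100, 5101]}
        )
        return GeneModelSet(meta, tss, exons)

    def _gwas(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos0", "p"])

    def test_variant_inside_exon_assigned_distance_zero(self, genes):
        gwas = self._gwas([("v1", "1", 1050, 1e-10)])
        got, table = nearest_exon_assign(gwas, genes)
        assert got == {"A"}
        assert table["distance"].iloc[0] == 0

    def test_closer_exon_wins(self, genes):
        gwas = self._gwas([("v1", "1", 1200, 1e-10)])  # 100 bp from A, 3800 from B
        got, _ = nearest_exon_assign(gwas, genes)
        assert got == {"A"}

    def test_equidistant_tie_reports_both(self, genes):
        # distance to A: pos - 1100 + 1; distance to B: 5001 - pos
        gwas = self._gwas([("v1", "1", 3049, 1e-10)])
        got, table = nearest_exon_assign(gwas, genes)
        assert got == {"A"}  # 1950 vs 1952
        gwas = self._gwas([("v2", "1", 3050, 1e-10)])
        got, table = nearest_exon_assign(gwas, genes)
        assert got == {"A", "B"}  # symmetric: 1951 vs 1951
        assert table["tie"].iloc[0]

    def test_only_significant_variants_used(self, genes):
        gwas = self._gwas([("v1", "1", 1050, 1e-7)])
        got, table = nearest_exon_assign(gwas, genes, p_threshold=1e-8)
        assert got == set() and table.empty

    def test_chromosome_without_exons_skipped(self, genes):
        gwas = self._gwas([("v1", "2", 1050, 1e-10)])
        got, table = nearest_exon_assign(gwas, genes)
        assert got == set()


class TestCompareSets:
    def test_identity_jaccard_one(self):
        out = compare_sets({"a", "b"}, {"a", "b"})
        assert out["jaccard"] == 1.0

    def test_disjoint(self):
        out = compare_sets({"a"}, {"b"})
        assert out["n_intersection"] == 0 and out["jaccard"] == 0.0

    def test_partial_overlap(self):
        out = compare_sets({"a", "b", "c"}, {"b", "c", "d"})
        assert out["n_intersection"] == 2
        assert out["jaccard"] == pytest.approx(0.5)


class TestPrecisionRecall:
    def test_enumerated_example(self):
        results = scores_df([("A", 0.9), ("B", 0.5), ("C", 0.4), ("D", 0.1)])
        out = precision_recall(results, {"A", "C"}, thresholds=np.array([0.3]))
        row = out.iloc[0]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(1.0)
        # background rate 2/4 -> fold = (2/3) / (1/2)
        assert row["fold_enrichment"] == pytest.approx(4 / 3)

    def test_zero_threshold_full_recall(self):
        results = scores_df([("A", 0.9), ("B", 0.5), ("C", 0.4), ("D", 0.1)])
        out = precision_recall(results, {"A", "C"}, thresholds=np.array([0.0]))
        assert out["recall"].iloc[0] == 1.0

    def test_reference_equal_universe_precision_one(self):
        results = scores_df([("A", 0.9), ("B", 0.5)])
        out = precision_recall(results, {"A", "B"})
        nonempty = out[out["n_prioritised"] > 0]
        assert (nonempty["precision"] == 1.0).all()

    def test_recall_and_n_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        results = scores_df([(f"g{i}", s) for i, s in enumerate(rng.random(100))])
        ref = set(rng.choice([f"g{i}" for i in range(100)], 30, replace=False))
        out = precision_recall(results, ref)
        assert (np.diff(out["recall"]) <= 1e-12).all()
        assert (np.diff(out["n_prioritised"]) <= 0).all()

    def test_reference_restricted_to_scored_genes(self):
        results = scores_df([("A", 0.9), ("B", 0.0)])
        out = precision_recall(results, {"A", "B"}, thresholds=np.array([0.5]))
        # B has score 0 -> excluded from the reference denominator
        assert out["recall"].iloc[0] == 1.0


class TestGsea:
    def test_top_gene_singleton_set_extreme_es(self):
        ranked = scores_df([(f"g{i}", 10 - i) for i in range(10)])
        out = gsea_preranked(ranked, {"top": {"g0"}}, n_perm=50, exponent=0.0, seed=1)
        assert out["es"].iloc[0] == pytest.approx(1.0)

    def test_es_matches_brute_force_small_instance(self):
        # N = 8, |S| = 3: recompute the weighted running sum longhand
        scores = np.array([5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        genes = [f"g{i}" for i in range(8)]
        members = {"g1", "g4", "g6"}
        ranked = scores_df(list(zip(genes, scores)))
        out = gsea_preranked(ranked, {"s": members}, n_perm=10, exponent=1.0, seed=0)
        hit_total = sum(s for g, s in zip(genes, scores) if g in members)
        running, best = 0.0, 0.0
        for g, s in zip(genes, scores):
            running += s / hit_total if g in members else -1.0 / 5
            if abs(running) > abs(best):
                best = running
        assert out["es"].iloc[0] == pytest.approx(best, abs=1e-12)

    def test_es_bounded_and_sign_flips_on_reversal(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        scores = np.sort(rng.random(40))[::-1]
        members = set(rng.choice(genes, 8, replace=False))
        fwd = gsea_preranked(scores_df(list(zip(genes, scores))), {"s": members}, n_perm=10, seed=0)
        # negating the metric reverses the ranking while each gene keeps |score|
        rev = gsea_preranked(
            scores_df(list(zip(genes, -scores))), {"s": members}, n_perm=10, seed=0
        )
        assert -1 <= fwd["es"].iloc[0] <= 1
        assert rev["es"].iloc[0] == pytest.approx(-fwd["es"].iloc[0], abs=1e-9)

    def test_whole_list_set_rejected(self):
        ranked = scores_df([("a", 2.0), ("b", 1.0)])
        with pytest.raises(CogsError):
            gsea_preranked(ranked, {"s": {"a", "b"}}, n_perm=10, seed=0)

    def test_nominal_p_uniform_under_null(self):
        # random sets against a fixed ranking: permutation-null oracle
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(100)]
        ranked = scores_df(list(zip(genes, np.sort(rng.random(100))[::-1])))
        pvals = []
        for rep in range(400):
            members = set(rng.choice(genes, 10, replace=False))
            out = gsea_preranked(ranked, {"s": members}, n_perm=200, seed=rep)
            pvals.append(out["p"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        ranked = scores_df(list(zip(genes, np.sort(rng.random(50))[::-1])))
        sets = {"s1": set(genes[3:9]), "s2": set(genes[20:40:2])}
        a = gsea_preranked(ranked, sets, n_perm=100, seed=9)
        b = gsea_preranked(ranked, sets, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestOra:
    def test_perfect_overlap_combinatorial_p(self):
        universe = {f"g{i}" for i in range(20)}
        annot = {"s": {f"g{i}" for i in range(5)}}
        out = ora_hypergeometric(set(annot["s"]), annot, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_overlap_at_expectation_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        annot = {"s": {f"g{i}" for i in range(20)}}
        drawn = {f"g{i}" for i in range(16, 36)}  # overlap 4 = expectation
        out = ora_hypergeometric(drawn, annot, universe)
        assert out["p"].iloc[0] > 0.3
        assert not out["significant"].iloc[0]

    def test_bh_adjustment_example(self):
        # BH on {0.01, 0.02, 0.03} -> all 0.03
        universe = {f"g{i}" for i in range(40)}
        out = pd.DataFrame({"p": [0.01, 0.02, 0.03]})
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(out["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_matches_exhaustive_enumeration_small_universe(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(25)]
        annot = {"s": set(rng.choice(universe, 8, replace=False))}
        drawn = set(rng.choice(universe, 10, replace=False))
        out = ora_hypergeometric(drawn, annot, set(universe))
        M, K, n = 25, 8, 10
        k = len(drawn & annot["s"])
        expected = sum(
            math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
            for j in range(k, min(K, n) + 1)
        )
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_prioritised_outside_universe_rejected(self):
        with pytest.raises(InvalidConfigError):
            ora_hypergeometric({"zz"}, {"s": {"a"}}, {"a", "b"})


class TestClustering:
    def test_planted_two_blocks_recovered_at_k_two(self):
        mat, labels = simulate_expression(
            [f"g{i}" for i in range(40)], n_samples=10, n_clusters=2, seed=6
        )
        assignments, best_k, diag = cluster_expression(mat, range(2, 6), seed=0)
        assert best_k == 2
        assert adjusted_rand_score(labels, assignments.to_numpy()) == 1.0

    def test_sample_order_invariance(self):
        mat, _ = simulate_expression([f"g{i}" for i in range(30)], n_samples=9, n_clusters=3, seed=8)
        a, k_a, _ = cluster_expression(mat, range(2, 5), seed=0)
        permuted = mat[mat.columns[::-1]]
        b, k_b, _ = cluster_expression(permuted, range(2, 5), seed=0)
        assert k_a == k_b
        assert adjusted_rand_score(a.to_numpy(), b.to_numpy()) == 1.0

    def test_degenerate_k_guarded(self):
        mat, _ = simulate_expression([f"g{i}" for i in range(5)], n_samples=6, n_clusters=2, seed=1)
        with pytest.raises(CogsError):
            cluster_expression(mat, range(5, 6), seed=0)  # k = n_genes

    def test_constant_gene_dropped(self, caplog):
        mat, _ = simulate_expression([f"g{i}" for i in range(20)], n_samples=8, n_clusters=2, seed=2)
        mat.iloc[0] = 3.0
        with caplog.at_level("INFO"):
            assignments, _, _ = cluster_expression(mat, range(2, 4), seed=0)
        assert "g0" not in assignments.index


class TestTopExpression:
    def test_quarter_kept_at_default_quantile(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(
            rng.random((100, 4)) + np.arange(100)[:, None],
            index=[f"g{i}" for i in range(100)],
        )
        kept = top_expression_filter(mat, quantile=0.75)
        assert len(kept) == 25

    def test_all_equal_keeps_ties(self):
        mat = pd.DataFrame(np.ones((8, 3)), index=[f"g{i}" for i in range(8)])
        assert len(top_expression_filter(mat)) == 8

    def test_empty_matrix_rejected(self):
        with pytest.raises(CogsError):
            top_expression_filter(pd.DataFrame())
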