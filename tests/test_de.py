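"""Rank-sum DE screen: exact/asymptotic p-values, BH adjustment, fold
changes, spatial similarity, and candidate ranking."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from _oracle import brute_bh, brute_rank_sum_p
from _util import norm_from_values, run_sim_analysis
from eibalance.descreen import (DEThresholds, de_table, fold_change,
                                per_gene_test, prioritize_candidates,
                                spatial_similarity)
from eibalance.setscore import ScoreMatrix
from eibalance.st_io import GeneSetCollection
from eibalance.stats import bh_adjust, rank_sum_test


class TestRankSum:
    def test_fully_separated_small_groups_exact_p(self):
        # most extreme of C(6,3)=20 assignments, two-sided: 2/20
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 2, 5], [2, 1, 5, 2])
        assert p >= 0.99

    def test_exact_path_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=int(rng.integers(2, 6))).tolist()
            y = rng.integers(0, 4, size=int(rng.integers(2, 6))).tolist()
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(brute_rank_sum_p(x, y))

    def test_asymptotic_path_agrees_with_scipy(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.5, 1, size=35)
        _, p = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_constant_gene_p_one_by_convention(self):
        nm = norm_from_values(np.ones((8, 2)))
        p = per_gene_test(nm, ["A"] * 4 + ["B"] * 4, "B", "A")
        assert (p == 1.0).all()

    def test_vectorized_matches_scalar_path(self, rng):
        values = rng.poisson(2.0, size=(30, 6)).astype(float)
        groups = np.array(["A"] * 14 + ["B"] * 16)
        nm = norm_from_values(values)
        p_vec = per_gene_test(nm, groups, "B", "A")
        for j in range(6):
            _, p = rank_sum_test(values[groups == "B", j],
                                 values[groups == "A", j])
            assert p_vec[j] == pytest.approx(p, rel=1e-9)


class TestBH:
    def test_step_up_small_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            np.testing.assert_allclose(bh_adjust(p), brute_bh(p.tolist()))

    def test_invariant_to_input_order(self, rng):
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFoldChange:
    def _nm_with_means(self, mean_con, mean_aff, n=5):
        # values are log1p of the de-logged quantities used for FC
        rows = [np.log1p(np.array(mean_con, dtype=float))] * n + \
               [np.log1p(np.array(mean_aff, dtype=float))] * n
        return norm_from_values(np.vstack(rows)), ["CON"] * n + ["DSS"] * n

    def test_doubling_is_fc_two(self):
        nm, groups = self._nm_with_means([10.0], [20.0])
        fc, abs_fc, direction = fold_change(nm, groups, "DSS", "CON",
                                            pseudocount=0.0)
        assert fc[0] == pytest.approx(2.0) and direction[0] == "up"

    def test_equal_means_never_pass_gate(self):
        nm, groups = self._nm_with_means([7.0], [7.0])
        _, abs_fc, _ = fold_change(nm, groups, "DSS", "CON", 0.0)
        assert abs_fc[0] == pytest.approx(1.0) and abs_fc[0] < 1.25

    def test_downregulation_symmetry(self):
        nm, groups = self._nm_with_means([10.0], [7.0])
        fc, abs_fc, direction = fold_change(nm, groups, "DSS", "CON", 0.0)
        assert fc[0] == pytest.approx(0.7)
        assert abs_fc[0] == pytest.approx(1 / 0.7)
        assert direction[0] == "down"

    def test_abs_fc_invariant_to_group_swap(self, rng):
        values = rng.poisson(3.0, size=(24, 8)).astype(float)
        nm = norm_from_values(np.log1p(values))
        groups = ["A"] * 12 + ["B"] * 12
        _, ab, _ = fold_change(nm, groups, "B", "A")
        _, ba, _ = fold_change(nm, groups, "A", "B")
        np.testing.assert_allclose(ab, ba)


class TestDETable:
    def test_gates_fc_and_padj(self):
        # three genes: fc~1.3 (pass, not top), fc~1.6 (top), fc~1.1 (fails)
        con = np.log1p(np.array([10.0, 10.0, 10.0]))
        aff = np.log1p(np.array([13.0, 16.0, 11.0]))
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 1e-4, size=(80, 3))
        values = np.vstack([np.tile(con, (40, 1)), np.tile(aff, (40, 1))])
        nm = norm_from_values(values + np.abs(jitter))
        groups = ["CON"] * 40 + ["DSS"] * 40
        de = de_table(nm, groups, "DSS", "CON").set_index("gene")
        assert bool(de.loc["g0", "pass_de"]) and not bool(de.loc["g0", "top_tier"])
        assert bool(de.loc["g1", "top_tier"])
        assert not bool(de.loc["g2", "pass_de"]) and de.loc["g2", "padj"] < 0.05

    def test_padj_never_below_p(self, rng):
        values = rng.poisson(2.0, size=(40, 30)).astype(float)
        nm = norm_from_values(np.log1p(values))
        de = de_table(nm, ["A"] * 20 + ["B"] * 20, "B", "A")
        assert (de["padj"] >= de["p"] - 1e-12).all()

    def test_sorted_by_padj_then_effect(self, rng):
        values = rng.poisson(2.0, size=(40, 30)).astype(float)
        nm = norm_from_values(np.log1p(values))
        de = de_table(nm, ["A"] * 20 + ["B"] * 20, "B", "A")
        assert de["padj"].is_monotonic_increasing


class TestSpatialSimilarity:
    def _sm(self, score):
        return ScoreMatrix(np.asarray(score, dtype=float)[:, None],
                           [f"bc{i}" for i in range(len(score))], ["glut"])

    def test_gene_equal_to_score_has_similarity_one(self):
        score = [0.1, 0.5, 0.3, 0.9, 0.7]
        values = np.column_stack([score, np.zeros(5)])
        nm = norm_from_values(values)
        sim = spatial_similarity(nm, self._sm(score), "glut", genes=["g0"])
        assert sim["g0"] == pytest.approx(1.0)

    def test_negated_ranks_give_minus_one(self):
        score = [0.1, 0.5, 0.3, 0.9, 0.7]
        values = np.column_stack([1.0 - np.asarray(score)])
        nm = norm_from_values(values)
        sim = spatial_similarity(nm, self._sm(score), "glut")
        assert sim["g0"] == pytest.approx(-1.0)

    def test_constant_gene_zero_with_warning(self):
        nm = norm_from_values(np.column_stack([np.ones(5)]))
        with pytest.warns(UserWarning, match="constant"):
            sim = spatial_similarity(nm, self._sm([1, 2, 3, 4, 5]), "glut")
        assert sim["g0"] == 0.0

    def test_constructed_tracker_gene_ranks_first(self):
        """A gene rewritten as a monotone transform of the glutamatergic
        score must top the similarity ranking of discovered genes."""
        bundle = run_sim_analysis(seed=7)
        nm, sm = bundle["norm_hip"], bundle["scores"]
        score = sm.column("Glutamatergic_synapse")
        values = nm.values.copy()
        j = nm.genes.index("Gene0100")
        values[:, j] = np.exp(score)  # strictly monotone transform
        nm2 = norm_from_values(values, barcodes=list(nm.barcodes),
                               genes=list(nm.genes))
        sim = spatial_similarity(nm2, sm, "Glutamatergic_synapse")
        assert sim.idxmax() == "Gene0100"
        assert sim["Gene0100"] == pytest.approx(1.0)


class TestPrioritize:
    def _de(self, rows):
        df = pd.DataFrame(rows)
        for col, default in [("pass_de", True), ("top_tier", True)]:
            if col not in df:
                df[col] = default
        return df

    def test_ordered_by_similarity_then_fold(self):
        de = self._de([
            {"gene": "a", "similarity": 0.4, "abs_fc": 2.0},
            {"gene": "b", "similarity": 0.9, "abs_fc": 1.6},
            {"gene": "c", "similarity": 0.4, "abs_fc": 3.0},
        ])
        sets = GeneSetCollection({"S": ["a", "b", "c"]})
        out = prioritize_candidates(de, sets, "S")
        assert out["gene"].tolist() == ["b", "c", "a"]

    def test_non_members_and_non_top_tier_excluded(self):
        de = self._de([
            {"gene": "a", "similarity": 0.9, "abs_fc": 2.0, "top_tier": False},
            {"gene": "x", "similarity": 0.9, "abs_fc": 2.0},
        ])
        sets = GeneSetCollection({"S": ["a"]})
        assert prioritize_candidates(de, sets, "S").empty


class TestRecovery:
    def test_spiked_genes_recovered_with_fdr_control(self):
        """30 spiked genes at fold 2 among 1000; the gate must recover
        nearly all of them with few false discoveries."""
        bundle = run_sim_analysis(seed=7, effect_glut=1.0, effect_gaba=1.0,
                                  receptor_boost=1.0, n_de_spike=30,
                                  de_spike_fold=2.0)
        gt = bundle["ground_truth"]
        de = bundle["de"].set_index("gene")
        truth = gt.genes.set_index("gene")["true_fold"].reindex(de.index)
        hits = de["pass_de"]
        recall = float(hits[truth > 1].mean())
        fdr = float((truth[hits] == 1).mean()) if hits.sum() else 0.0
        assert recall >= 0.9
        assert fdr <= 0.1
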