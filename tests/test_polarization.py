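import copy

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoshift import (GeneSet, ValidationError, bin_genes_by_expression,
                       category_proportions, classify_cluster,
                       classify_clusters, geneset_activity_test, log_normalize,
                       module_score)

from conftest import annotations_for, make_count_matrix


def norm_from_dense(dense, genes=None):
    cm = make_count_matrix(np.ones_like(np.asarray(dense)), genes=genes)
    norm = log_normalize(cm)
    norm.values = sp.csr_matrix(np.asarray(dense, float))
    return norm


class TestBinning:
    def test_one_gene_per_bin_ordered_by_mean(self):
        dense = np.arange(24, dtype=float)[:, None] * np.ones((1, 3))
        norm = norm_from_dense(dense)
        bins = bin_genes_by_expression(norm, nbin=24)
        assert sorted(bins.unique().tolist()) == list(range(24))
        # lowest-expression gene in bin 0, highest in bin 23
        assert bins["g0"] == 0 and bins["g23"] == 23

    def test_tied_means_follow_symbol_order(self):
        dense = np.ones((4, 2))
        norm = norm_from_dense(dense, genes=["d", "c", "b", "a"])
        bins = bin_genes_by_expression(norm, nbin=2)
        assert bins["a"] == 0 and bins["b"] == 0
        assert bins["c"] == 1 and bins["d"] == 1

    def test_invariant_to_gene_input_order(self, small_norm):
        bins = bin_genes_by_expression(small_norm, nbin=10)
        perm = np.random.default_rng(0).permutation(small_norm.n_genes)
        shuffled = copy.copy(small_norm)
        shuffled.genes = [small_norm.genes[i] for i in perm]
        shuffled.values = small_norm.values[perm]
        bins2 = bin_genes_by_expression(shuffled, nbin=10)
        assert bins.sort_index().equals(bins2.sort_index())

    def test_nbin_exceeding_gene_count_rejected(self):
        norm = norm_from_dense(np.ones((4, 2)))
        with pytest.raises(ValidationError):
            bin_genes_by_expression(norm, nbin=5)


class TestModuleScore:
    def test_uniform_expression_scores_zero(self):
        norm = norm_from_dense(np.full((30, 5), 2.0))
        res = module_score(norm, GeneSet("s", ["g0", "g1"]), nbin=3, nctrl=10, seed=0)
        np.testing.assert_allclose(res.scores.to_numpy(), 0.0, atol=1e-12)

    def test_control_pool_equal_to_set_scores_exactly_zero(self, small_norm, signatures):
        m1 = signatures["M1"]
        present = [g for g in m1.genes if g in set(small_norm.genes)]
        res = module_score(small_norm, m1, control_genes=present)
        np.testing.assert_allclose(res.scores.to_numpy(), 0.0, atol=1e-12)

    def test_same_seed_reproduces(self, small_norm, signatures):
        a = module_score(small_norm, signatures["M1"], seed=5)
        b = module_score(small_norm, signatures["M1"], seed=5)
        assert a.control_genes_used == b.control_genes_used
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_planted_program_scores_near_delta(self, small_cohort, small_norm,
                                               signatures):
        """The cluster carrying a delta=1 M1 program scores ~1 above the rest."""
        _, ann, truth, _ = small_cohort
        res = module_score(small_norm, signatures["M1"], seed=2)
        by = res.scores.groupby(ann.set_index("cell")["cluster"]).mean()
        activity = by["C04"] - by.drop("C04").mean()
        assert activity == pytest.approx(1.0, abs=0.15)

    def test_absent_set_rejected(self, small_norm):
        with pytest.raises(ValidationError):
            module_score(small_norm, GeneSet("ghost", ["NOPE1", "NOPE2"]))


class TestActivityTest:
    def test_extreme_concentration_reaches_floor(self):
        scores = pd.Series(np.r_[np.ones(20), np.zeros(180)],
                           index=[f"c{i}" for i in range(200)])
        ann = pd.DataFrame({"cell": scores.index,
                            "sample_id": "s1", "group": "small",
                            "cluster": ["A"] * 20 + ["B"] * 180})
        act, p = geneset_activity_test(scores, ann, "A", n_perm=200, seed=0)
        assert act == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_two_cluster_partition_antisymmetry(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=100), index=[f"c{i}" for i in range(100)])
        ann = pd.DataFrame({"cell": scores.index, "sample_id": "s", "group": "g",
                            "cluster": ["A"] * 30 + ["B"] * 70})
        a, _ = geneset_activity_test(scores, ann, "A", n_perm=200, seed=0)
        b, _ = geneset_activity_test(scores, ann, "B", n_perm=200, seed=0)
        assert a == pytest.approx(-b)

    def test_null_rejection_rate_calibrated(self):
        """Scores independent of labels: rejection at 0.05 stays near 0.05."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            scores = pd.Series(rng.normal(size=120),
                               index=[f"c{i}" for i in range(120)])
            labels = np.array(["A"] * 30 + ["B"] * 90)
            rng.shuffle(labels)
            ann = pd.DataFrame({"cell": scores.index, "sample_id": "s",
                                "group": "g", "cluster": labels})
            _, p = geneset_activity_test(scores, ann, "A", n_perm=200, seed=1)
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 3 * se

    def test_low_n_perm_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        ann = pd.DataFrame({"cell": ["a", "b"], "sample_id": "s", "group": "g",
                            "cluster": ["A", "B"]})
        with pytest.raises(ValidationError):
            geneset_activity_test(scores, ann, "A", n_perm=10)


class TestClassification:
    @pytest.mark.parametrize("m1,m2,want", [
        ((0.5, 0.001), (0.4, 0.002), "Mixed"),
        ((0.5, 0.001), (-0.2, 0.001), "M1-like"),
        ((-0.5, 0.001), (0.2, 0.001), "M2-like"),
        ((0.0, 1.0), (0.0, 1.0), "Neither"),
        ((0.5, 0.5), (0.4, 0.5), "Neither"),   # activity without significance
    ])
    def test_rule_examples(self, m1, m2, want):
        assert classify_cluster(m1, m2, alpha=0.01) == want

    @given(a1=st.floats(-2, 2), p1=st.floats(0, 1),
           a2=st.floats(-2, 2), p2=st.floats(0, 1),
           alpha=st.sampled_from([0.01, 0.05]))
    @settings(max_examples=200, deadline=None)
    def test_pure_decision_rule(self, a1, p1, a2, p2, alpha):
        got = classify_cluster((a1, p1), (a2, p2), alpha=alpha)
        m1_pos = a1 > 0 and p1 < alpha
        m2_pos = a2 > 0 and p2 < alpha
        want = ("Mixed" if m1_pos and m2_pos else
                "M1-like" if m1_pos else
                "M2-like" if m2_pos else "Neither")
        assert got == want

    def test_classify_clusters_on_planted_cohort(self, small_cohort, small_norm,
                                                 signatures):
        _, ann, truth, _ = small_cohort
        m1 = module_score(small_norm, signatures["M1"], seed=0)
        m2 = module_score(small_norm, signatures["M2"], seed=1)
        calls = classify_clusters(m1, m2, ann, alpha=0.01, n_perm=300, seed=0)
        got = dict(zip(calls.cluster, calls.category))
        assert got["C04"] == "M1-like"


class TestCategoryProportions:
    def test_single_sample_split(self):
        ann = pd.DataFrame({
            "cell": [f"c{i}" for i in range(100)],
            "sample_id": "s1", "group": "small",
            "cluster": ["A"] * 30 + ["B"] * 70,
        })
        out = category_proportions({"A": "Neither", "B": "M1-like"}, ann)
        sub = out.set_index("category")["percent"]
        assert sub["Neither"] == pytest.approx(30.0)
        assert sub["M1-like"] == pytest.approx(70.0)
        assert sub["M2-like"] == 0.0

    def test_percentages_sum_to_hundred(self, small_cohort):
        _, ann, truth, _ = small_cohort
        out = category_proportions(truth.planted_category, ann)
        sums = out.groupby("sample_id")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_unclassified_cluster_rejected(self, small_cohort):
        _, ann, _, _ = small_cohort
        with pytest.raises(ValidationError):
            category_proportions({"C00": "Neither"}, ann)
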