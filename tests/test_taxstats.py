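"""Inference layer: permutation tests, Holm, the normality gate, LDA/QDA
with LOO, PC-count selection, query posteriors, geography/chronology."""

import numpy as np
import pytest
from scipy import stats

from paleogm import (
    DiscriminantClassifier,
    chrono_group_test,
    classify_query,
    fit_da_loo,
    geo_correlation,
    holm_adjust,
    normality_gate,
    permutation_test_pairs,
    select_pc_count,
)
from paleogm.taxstats import InsufficientDataError, WindowEmptyError


def two_gaussian_groups(rng, n=30, sep=0.0, d=3):
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d))
    b[:, 0] += sep
    scores = np.vstack([a, b])
    labels = np.array(["A"] * n + ["B"] * n)
    return scores, labels


class TestPermutation:
    def test_minimum_attainable_p(self, rng):
        scores, labels = two_gaussian_groups(rng, n=20, sep=50.0)
        rep = permutation_test_pairs(scores, labels, n_permutations=10_000,
                                     rng=1)
        assert rep.p_raw[0] == pytest.approx(1.0 / 10_001)

    def test_null_p_values_uniform(self):
        """Calibration: under a common distribution the permutation p is
        U(0,1) (200 replicate datasets, N = 1,000)."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            scores, labels = two_gaussian_groups(r, n=12, sep=0.0)
            rep = permutation_test_pairs(scores, labels,
                                         n_permutations=1_000, rng=seed)
            ps.append(rep.p_raw[0])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_seed_reproducibility(self, rng):
        scores, labels = two_gaussian_groups(rng, n=10, sep=1.0)
        r1 = permutation_test_pairs(scores, labels, 500, rng=42)
        r2 = permutation_test_pairs(scores, labels, 500, rng=42)
        assert np.array_equal(r1.p_raw, r2.p_raw)

    def test_all_pairs_reported_with_holm(self, rng):
        scores = rng.normal(size=(30, 3))
        labels = np.repeat(["A", "B", "C"], 10)
        rep = permutation_test_pairs(scores, labels, 200, rng=0)
        assert len(rep.pairs) == 3
        assert np.all(rep.p_holm >= rep.p_raw)
        assert np.all(rep.p_raw >= 1.0 / 201.0)

    def test_small_group_rejected(self, rng):
        scores = rng.normal(size=(3, 3))
        with pytest.raises(InsufficientDataError):
            permutation_test_pairs(scores, ["A", "A", "B"], 100)


class TestHolm:
    def test_hand_computed_ladder(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06], atol=1e-12)

    def test_never_decreases_and_monotone(self, rng):
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestNormalityGate:
    def test_lognormal_scores_trigger_qda(self, rng):
        scores = np.column_stack([
            rng.lognormal(size=50), rng.normal(size=50), rng.normal(size=50)])
        labels = np.array(["A"] * 25 + ["B"] * 25)
        assert normality_gate(scores, labels) == "QDA"

    def test_gaussian_scores_choose_lda(self):
        r = np.random.default_rng(5)
        scores = r.normal(size=(100, 3))
        labels = np.array(["A"] * 50 + ["B"] * 50)
        assert normality_gate(scores, labels) == "LDA"

    def test_constant_column_rejected(self, rng):
        scores = np.column_stack([np.ones(20), rng.normal(size=20),
                                  rng.normal(size=20)])
        labels = np.array(["A"] * 10 + ["B"] * 10)
        with pytest.raises(InsufficientDataError, match="constant"):
            normality_gate(scores, labels)

    def test_tiny_group_rejected(self, rng):
        scores = rng.normal(size=(5, 3))
        with pytest.raises(InsufficientDataError):
            normality_gate(scores, np.array(["A", "A", "A", "B", "B"]))


class TestLOODiscriminant:
    def test_perfect_separation_full_accuracy(self, rng):
        scores, labels = two_gaussian_groups(rng, n=30, sep=6.0)
        rep = fit_da_loo(scores, labels, "LDA")
        assert rep.loo_accuracy == 1.0
        assert rep.confusion.to_numpy().trace() == 60

    def test_shuffled_labels_near_chance(self):
        """Averaged over shuffles, LOO accuracy on label-permuted data sits
        inside the 99% binomial band around chance (single shuffles of
        clustered data can exploit chance imbalance, so we average)."""
        r = np.random.default_rng(11)
        scores, labels = two_gaussian_groups(r, n=40, sep=6.0)
        n_rep = 25
        accs = [fit_da_loo(scores, r.permutation(labels), "LDA").loo_accuracy
                for _ in range(n_rep)]
        band = 2.58 * np.sqrt(0.25 / (80 * n_rep))
        # chance-imbalance exploitation inflates the null mean by O(1/sqrt(n))
        assert abs(np.mean(accs) - 0.5) < band + 0.06

    def test_accuracy_increases_with_separation(self):
        accs = []
        for sep in (0.0, 2.0, 6.0):
            vals = []
            for seed in range(5):
                r = np.random.default_rng(100 + seed)
                scores, labels = two_gaussian_groups(r, n=25, sep=sep)
                vals.append(fit_da_loo(scores, labels, "QDA").loo_accuracy)
            accs.append(np.mean(vals))
        assert accs[0] < accs[1] < accs[2]
        assert accs[2] == 1.0

    def test_qda_needs_per_group_n_above_k(self, rng):
        scores = rng.normal(size=(6, 3))
        labels = np.array(["A"] * 3 + ["B"] * 3)
        with pytest.raises(InsufficientDataError, match="per-group"):
            fit_da_loo(scores, labels, "QDA")


class TestSelectPCCount:
    def test_separable_on_pc1_returns_window_floor(self, rng):
        """Groups separable on PC1 alone and a window starting at k = 2:
        every k ties at perfect accuracy, so the smallest is returned."""
        scores, labels = two_gaussian_groups(rng, n=25, sep=8.0, d=6)
        var = np.array([0.40, 0.32, 0.10, 0.06, 0.07, 0.05])
        k = select_pc_count(var, scores, labels, "LDA")
        assert k == 2

    def test_tie_takes_smallest(self, rng):
        scores, labels = two_gaussian_groups(rng, n=20, sep=10.0, d=5)
        var = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
        assert select_pc_count(var, scores, labels, "LDA") == 3

    def test_cumulative_jump_over_window(self, rng):
        # 0.65 -> 0.92 jump: the single k reaching 70% is used
        scores, labels = two_gaussian_groups(rng, n=20, sep=5.0, d=3)
        var = np.array([0.65, 0.27, 0.08])
        assert select_pc_count(var, scores, labels, "LDA") == 2

    def test_empty_window_reported(self, rng):
        # window demands k = 3 PCs but QDA with 3-member groups needs
        # k < 3: the truncated window is empty
        scores, labels = two_gaussian_groups(rng, n=3, sep=5.0, d=4)
        var = np.array([0.25, 0.25, 0.25, 0.25])
        with pytest.raises(WindowEmptyError):
            select_pc_count(var, scores, labels, "QDA")


class TestQueryPosteriors:
    def test_query_at_group_mean_confident(self, rng):
        scores, labels = two_gaussian_groups(rng, n=30, sep=8.0)
        mean_a = scores[labels == "A"].mean(axis=0)
        post = classify_query(scores, labels, mean_a, "LDA")
        assert post["A"].iloc[0] > 0.99
        assert post.iloc[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_groups_symmetric_posterior(self, rng):
        block = rng.normal(size=(20, 3))
        scores = np.vstack([block, block])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        post = classify_query(scores, labels, np.zeros(3), "LDA")
        assert post.iloc[0]["A"] == pytest.approx(0.5, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        scores, labels = two_gaussian_groups(rng, n=25, sep=2.0)
        queries = rng.normal(size=(10, 3)) * 3
        post = classify_query(scores, labels, queries, "QDA")
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        scores, labels = two_gaussian_groups(rng, n=20, sep=2.0)
        with pytest.raises(ValueError, match="scores"):
            classify_query(scores, labels, np.zeros(2), "LDA", n_pcs=3)


class TestDiscriminantClassifier:
    def test_auto_gate_and_report(self, rng):
        scores, labels = two_gaussian_groups(rng, n=40, sep=6.0, d=5)
        var = np.array([0.5, 0.2, 0.12, 0.1, 0.08])
        clf = DiscriminantClassifier(model="auto").fit(
            scores, labels, variance_ratio=var)
        assert clf.model_ in ("LDA", "QDA")
        assert clf.loo_accuracy_ == 1.0
        rep = clf.report(np.zeros((1, 5)), ["query"])
        assert rep.query_posteriors.shape == (1, 2)
        assert rep.query_posteriors.loc["query"].sum() == pytest.approx(1.0)

    def test_params_roundtrip(self):
        clf = DiscriminantClassifier(model="LDA", n_pcs=4)
        clf2 = DiscriminantClassifier().set_params(**clf.get_params())
        assert clf2.model == "LDA" and clf2.n_pcs == 4


class TestGeoCorrelation:
    def test_exactly_linear_in_longitude(self, rng):
        n = 15
        lon = np.linspace(-5, 30, n)
        lat = rng.normal(45, 3, size=n)
        scores = np.column_stack([2.0 * lon + 1.0, rng.normal(size=n),
                                  rng.normal(size=n)])
        rep = geo_correlation(scores, lat, lon)
        row = rep[(rep.coordinate == "longitude") & (rep.pc == 1)].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-9)
        assert row.p < 1e-6

    def test_null_type_i_error_near_alpha(self):
        hits, med = [], []
        for seed in range(1000):
            r = np.random.default_rng(seed)
            scores = r.normal(size=(12, 1))
            lat = r.normal(45, 3, size=12)
            lon = r.normal(10, 5, size=12)
            rep = geo_correlation(scores, lat, lon, n_pcs=1)
            row = rep[rep.coordinate == "longitude"].iloc[0]
            hits.append(row.p < 0.05)
            med.append(abs(row.r))
        assert abs(np.mean(hits) - 0.05) < 0.02
        assert np.median(med) < 0.4

    def test_constant_latitude_rejected(self, rng):
        scores = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="latitude"):
            geo_correlation(scores, np.full(10, 45.0),
                            rng.normal(size=10))


class TestChronoGroupTest:
    def test_null_p_uniform(self):
        ps = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            scores = r.normal(size=(16, 1))
            mis = np.array(["early"] * 8 + ["classic"] * 8)
            rep = chrono_group_test(scores, mis, n_pcs=1)
            ps.append(rep.p.iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_anova_equals_pooled_t_test(self):
        r = np.random.default_rng(3)
        a = r.normal(0, 1, size=12)
        b = r.normal(0.5, 1, size=9)
        scores = np.concatenate([a, b])[:, None]
        mis = np.array(["early"] * 12 + ["classic"] * 9)
        rep = chrono_group_test(scores, mis, n_pcs=1)
        assert rep.branch.iloc[0] == "anova"
        t = stats.ttest_ind(a, b, equal_var=True)
        assert rep.p.iloc[0] == pytest.approx(t.pvalue, abs=1e-9)

    def test_lognormal_takes_kruskal_branch(self, rng):
        scores = np.concatenate([rng.lognormal(0, 1.5, size=25),
                                 rng.lognormal(1, 1.5, size=25)])[:, None]
        mis = np.array(["early"] * 25 + ["classic"] * 25)
        rep = chrono_group_test(scores, mis, n_pcs=1)
        assert rep.branch.iloc[0] == "kruskal-wallis"

    def test_single_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            chrono_group_test(rng.normal(size=(6, 3)), ["early"] * 6)
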