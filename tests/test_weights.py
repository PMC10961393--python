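"""Haufe transform, bootstrap concordance, BCa intervals, sub-network counts."""

import numpy as np
import pytest
from scipy import stats

from intrav1.connectivity import partition_subnetworks
from intrav1.mvpa import ConditionPair, train_svm
from intrav1.weights import (
    TransformedWeightMap,
    analyze_weight_maps,
    assemble_contingency,
    bca_ci,
    bootstrap_weight_maps,
    concordance_samples,
    haufe_transform,
    heterogeneity_test,
    kendalls_w,
    subnetwork_counts,
    summarize_maps,
)


class _Model:
    def __init__(self, retained, w):
        self.retained = np.asarray(retained)
        self.w = np.asarray(w, float)


class TestHaufe:
    def test_whitened_features_leave_weights_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 3))
        model = _Model([0, 1, 2], [1.0, -2.0, 0.5])
        a = haufe_transform(model, X).values
        assert np.allclose(a, model.w, atol=0.15)

    def test_matches_direct_covariance_multiply(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        model = _Model([1, 2, 4], [0.3, -1.0, 2.0])
        a = haufe_transform(model, X).values
        cov = np.cov(X[:, [1, 2, 4]], rowvar=False)
        expected = cov @ model.w
        assert np.allclose(a[[1, 2, 4]], expected, atol=1e-12)
        assert a[0] == 0 and a[3] == 0

    def test_noise_canceling_filter_pair_shrinks(self):
        # two perfectly anti-correlated features with opposing weights act
        # as a noise filter; their forward-model activations collapse
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        X = np.column_stack([x, -x + 1e-6 * rng.normal(size=200)])
        model = _Model([0, 1], [5.0, -5.0])
        a = haufe_transform(model, X).values
        # closed form: Sigma = [[1, -1], [-1, 1]] v -> a = (w1 - w2) * [v, -v]
        assert np.abs(a).max() < 2 * np.abs(model.w).max() * np.var(x) * 1.01
        sigma = np.cov(X, rowvar=False)
        assert np.allclose(a, sigma @ model.w, atol=1e-10)


class TestKendallW:
    def test_identical_rankings_give_one(self):
        scores = np.vstack([np.arange(10.0)] * 3)
        assert kendalls_w(scores) == pytest.approx(1.0)

    def test_reversed_pair_gives_zero(self):
        scores = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
        assert kendalls_w(scores) == pytest.approx(0.0)
        # formula oracle: W = (1 + rho_spearman) / 2 for m = 2
        rho = stats.spearmanr(scores[0], scores[1]).statistic
        assert kendalls_w(scores) == pytest.approx((1 + rho) / 2)

    def test_random_pairs_average_one_half(self):
        rng = np.random.default_rng(3)
        ws = [
            kendalls_w(rng.normal(size=(2, 100))) for _ in range(500)
        ]
        assert abs(np.mean(ws) - 0.5) < 0.02

    def test_ties_handled_with_midranks(self):
        scores = np.array([[1.0, 1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]])
        w = kendalls_w(scores)
        assert 0.0 < w <= 1.0

    def test_all_tied_rater_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            kendalls_w(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


class TestBCa:
    def test_zero_bias_zero_accel_reduces_to_percentiles(self):
        rng = np.random.default_rng(4)
        boot = rng.normal(size=4001)
        lo, hi = bca_ci(boot, float(np.median(boot)))
        assert lo == pytest.approx(np.quantile(np.sort(boot), 0.025), abs=0.02)
        assert hi == pytest.approx(np.quantile(np.sort(boot), 0.975), abs=0.02)

    def test_symmetric_replicates_match_percentile_interval(self):
        rng = np.random.default_rng(5)
        boot = rng.normal(0.0, 1.0, 2000)
        lo, hi = bca_ci(boot, 0.0)
        assert abs(lo - np.quantile(boot, 0.025)) < boot.std() / 5
        assert abs(hi - np.quantile(boot, 0.975)) < boot.std() / 5

    def test_degenerate_replicates_collapse_to_point(self):
        assert bca_ci(np.full(200, 1.3), 1.3) == (1.3, 1.3)

    def test_coverage_on_normal_mean(self):
        rng = np.random.default_rng(6)
        n, covered, sims = 30, 0, 300
        for _ in range(sims):
            sample = rng.normal(size=n)
            idx = rng.integers(0, n, (300, n))
            boot = sample[idx].mean(axis=1)
            jack = np.array(
                [np.delete(sample, i).mean() for i in range(n)]
            )
            lo, hi = bca_ci(boot, sample.mean(), jackknife_stats=jack)
            covered += lo <= 0.0 <= hi
        assert 0.92 * sims <= covered <= 0.98 * sims


def _replicates(maps_a, maps_b):
    return [
        (TransformedWeightMap(a, "A->B", i), TransformedWeightMap(b, "B->A", i))
        for i, (a, b) in enumerate(zip(maps_a, maps_b))
    ]


class TestSummaries:
    def test_identical_replicates_reproduce_map(self):
        base = np.array([0.0, 1.0, -2.0, 3.0, 0.5, -0.1] * 20)
        reps = _replicates([base] * 5, [base] * 5)
        summary = summarize_maps(reps)
        assert np.allclose(summary.median_map, base)
        assert concordance_samples(reps).min() == pytest.approx(1.0)

    def test_tail_sizes_follow_ceiling_rule(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=1000)  # all nonzero
        reps = _replicates([base] * 3, [base] * 3)
        summary = summarize_maps(reps)
        assert summary.local_edges.size == 25
        assert summary.global_edges.size == 25
        assert not set(summary.local_edges) & set(summary.global_edges)
        assert summary.median_map[summary.local_edges].min() > \
            summary.median_map[summary.global_edges].max()

    def test_sign_flip_swaps_tails(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=400)
        s1 = summarize_maps(_replicates([base] * 3, [base] * 3))
        s2 = summarize_maps(_replicates([-base] * 3, [-base] * 3))
        assert np.array_equal(s1.local_edges, s2.global_edges)
        assert np.array_equal(s1.global_edges, s2.local_edges)

    def test_scale_invariance_of_selection(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=300)
        s1 = summarize_maps(_replicates([base] * 2, [base] * 2))
        s2 = summarize_maps(_replicates([7.3 * base] * 2, [7.3 * base] * 2))
        assert np.array_equal(s1.local_edges, s2.local_edges)
        assert np.array_equal(s1.global_edges, s2.global_edges)


class TestBootstrap:
    def _pair(self, seed, n_subjects=8, n_edges=40, gap=1.5):
        rng = np.random.default_rng(seed)
        X = np.abs(rng.normal(0.3, 0.3, (n_subjects, 2, n_edges)))
        X[:, 1, :5] += gap
        return ConditionPair(
            subjects=tuple(f"s{i}" for i in range(n_subjects)),
            conditions=("EG", "EL"),
            labels=("Global", "Local"),
            X=X,
        )

    def test_fixed_seed_reproducible(self):
        pair = self._pair(0)
        r1 = bootstrap_weight_maps(pair, pair, n_boot=3, seed=5)
        r2 = bootstrap_weight_maps(pair, pair, n_boot=3, seed=5)
        for (a1, b1), (a2, b2) in zip(r1, r2):
            assert np.array_equal(a1.values, a2.values)
            assert np.array_equal(b1.values, b2.values)

    def test_planted_edge_activation_consistent_with_full_sample(self):
        pair = self._pair(1, n_subjects=15)
        X, y, _ = pair.flat()
        from intrav1.mvpa import ttest_select

        retained = ttest_select(X, y)
        model = train_svm(X, y, retained)
        full = haufe_transform(model, X).values
        reps = bootstrap_weight_maps(pair, pair, n_boot=100, seed=2)
        boots = np.array([a.values[0] for a, _ in reps])
        se = boots.std()
        assert abs(boots.mean() - full[0]) < 3 * se + 1e-9

    def test_concordant_directions_beat_chance(self):
        pair_a = self._pair(3, n_subjects=12)
        pair_b = self._pair(4, n_subjects=12)  # same planted topology
        pair_b = ConditionPair(
            subjects=pair_a.subjects, conditions=("UG", "UL"),
            labels=pair_a.labels, X=pair_b.X,
        )
        reps = bootstrap_weight_maps(pair_a, pair_b, n_boot=40, seed=6)
        assert np.median(concordance_samples(reps)) > 0.5


class TestCounts:
    def test_counts_conserve_tail_sizes(self, small_map):
        partition = partition_subnetworks(small_map)
        rng = np.random.default_rng(10)
        base = rng.normal(size=partition.n_edges)
        summary = summarize_maps(_replicates([base] * 3, [base] * 3))
        counts = subnetwork_counts(summary, partition)
        assert sum(counts["Local"].values()) == summary.local_edges.size
        assert sum(counts["Global"].values()) == summary.global_edges.size

    def test_contingency_shape(self, small_map):
        partition = partition_subnetworks(small_map)
        rng = np.random.default_rng(11)
        base = rng.normal(size=partition.n_edges)
        summary = summarize_maps(_replicates([base] * 3, [base] * 3))
        counts = subnetwork_counts(summary, partition)
        table = assemble_contingency({"CR": counts, "HRFc": counts, "FIR": counts})
        assert table.shape == (3, 2, 10)
        assert table.sum() == 3 * (summary.local_edges.size + summary.global_edges.size)


class TestHeterogeneity:
    def test_disjoint_one_hot_distributions_rejected(self):
        a = np.zeros(10)
        a[0] = 50
        b = np.zeros(10)
        b[9] = 50
        stat, p = heterogeneity_test(np.vstack([a, b]), n_mc=2000, seed=0)
        assert p < 1e-3  # Monte-Carlo floor; chi2 tail oracle gives << 1e-6
        assert stat > 90

    def test_identical_large_tables_calibrated(self):
        rng = np.random.default_rng(12)
        probs = np.full(10, 0.1)
        rejections = 0
        sims = 400
        for _ in range(sims):
            tables = rng.multinomial(300, probs, size=3)
            _, p = heterogeneity_test(tables, seed=1)
            rejections += p < 0.05
        assert 0.02 * sims <= rejections <= 0.09 * sims

    def test_single_table_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            heterogeneity_test(np.ones((1, 10)))


def test_analyze_weight_maps_end_to_end():
    rng = np.random.default_rng(13)
    X = np.abs(rng.normal(0.3, 0.3, (10, 2, 50)))
    X[:, 1, :4] += 1.0
    pair = ConditionPair(
        subjects=tuple(f"s{i}" for i in range(10)),
        conditions=("EG", "EL"), labels=("Global", "Local"), X=X,
    )
    summary = analyze_weight_maps(pair, pair, n_boot=60, seed=7)
    assert summary.w_ci[0] <= np.median(summary.kendall_w_samples) <= summary.w_ci[1]
    assert summary.kendall_w_samples.size == 60
    assert summary.local_edges.size >= 1
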