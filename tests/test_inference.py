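import numpy as np
import pytest

import chronodecode as cd
from oracles import exhaustive_signflip_pointwise_p


class TestClusterPermutationTest:
    def test_pointwise_p_matches_exhaustive_enumeration(self):
        """Monte-Carlo sign-flip p-values converge to the exact 2^P values."""
        rng = np.random.default_rng(5)
        effects = rng.normal(1.0, 2.0, size=(8, 6))
        exact = exhaustive_signflip_pointwise_p(effects)
        res = cd.cluster_permutation_test(effects + 50.0, n_permutations=20000, seed=0)
        np.testing.assert_allclose(res.pointwise_p, exact, atol=0.012)

    def test_all_at_chance_gives_no_clusters(self):
        values = np.full((12, 40), 50.0)
        res = cd.cluster_permutation_test(values, n_permutations=500, seed=1)
        assert not res.significant_mask.any()
        assert res.onset_ms() is None

    def test_constant_effect_spans_full_epoch(self):
        values = np.full((10, 30), 60.0)
        res = cd.cluster_permutation_test(values, n_permutations=1000, seed=2)
        assert res.significant_mask.all()
        assert len([c for c in res.clusters if c.significant]) == 1
        assert res.clusters[0].size == 30

    def test_monotonicity_of_significant_mask(self):
        rng = np.random.default_rng(3)
        base = 50.0 + rng.normal(0, 1.5, size=(15, 60))
        base[:, 20:35] += 2.0
        small = cd.cluster_permutation_test(base, n_permutations=1000, seed=7)
        boosted = base.copy()
        boosted[:, 20:35] += 3.0
        big = cd.cluster_permutation_test(boosted, n_permutations=1000, seed=7)
        assert (big.significant_mask | ~small.significant_mask).all()

    def test_participant_order_irrelevant(self):
        """Reordering participants leaves the inference unchanged (the
        observed statistic exactly; the Monte-Carlo null within tolerance)."""
        rng = np.random.default_rng(4)
        values = 50.0 + rng.normal(0, 2.0, size=(14, 25))
        values[:, 8:18] += 4.0  # clear effect, decision far from threshold
        a = cd.cluster_permutation_test(values, n_permutations=2000, seed=9)
        b = cd.cluster_permutation_test(values[::-1], n_permutations=2000, seed=9)
        np.testing.assert_array_equal(a.significant_mask, b.significant_mask)
        np.testing.assert_allclose(a.pointwise_p, b.pointwise_p, atol=0.03)

    def test_t_statistic_variant(self):
        rng = np.random.default_rng(6)
        values = 50.0 + rng.normal(1.5, 1.0, size=(16, 30))
        res = cd.cluster_permutation_test(values, n_permutations=2000, seed=0,
                                          statistic="t")
        assert res.significant_mask.any()

    def test_low_permutation_count_warns(self):
        values = np.full((4, 5), 51.0)
        with pytest.warns(RuntimeWarning, match="resolve"):
            cd.cluster_permutation_test(values, n_permutations=10, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        values = 50.0 + rng.normal(0.5, 2.0, size=(10, 20))
        a = cd.cluster_permutation_test(values, n_permutations=500, seed=3)
        b = cd.cluster_permutation_test(values, n_permutations=500, seed=3)
        np.testing.assert_array_equal(a.pointwise_p, b.pointwise_p)
        assert a.clusters == b.clusters

    def test_accepts_accuracy_timecourse_with_time_axis(self):
        time_ms = np.arange(0.0, 100.0, 5.0)
        values = np.full((8, time_ms.size), 50.0)
        values[:, 4:10] = 65.0
        acc = cd.AccuracyTimecourse(values=values, time_ms=time_ms)
        res = cd.cluster_permutation_test(acc, n_permutations=1000, seed=0)
        assert res.onset_ms() == 20.0
        assert res.offset_ms() == 45.0

    def test_min_participants(self):
        with pytest.raises(ValueError, match="2 participants"):
            cd.cluster_permutation_test(np.full((1, 10), 55.0))


class TestBootstrapPeakLatency:
    def _curves(self, peak_idx, n_participants=24, n_t=100, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n_t, dtype=float)
        base = 60.0 - 0.004 * (t - peak_idx) ** 2
        return base[None, :] + rng.normal(0, sd, size=(n_participants, n_t))

    def test_planted_peak_order_detected(self):
        a = self._curves(peak_idx=30, seed=1)  # early peak
        b = self._curves(peak_idx=80, seed=2)  # late peak
        test = cd.bootstrap_peak_latency_difference(a, b, n_bootstrap=1000, seed=0)
        assert test.peak_ms_a < test.peak_ms_b
        assert test.p_b_later > 0.95
        assert test.p_a_later < 0.05

    def test_identical_conditions_degenerate_p_zero(self):
        a = self._curves(peak_idx=50, seed=3)
        test = cd.bootstrap_peak_latency_difference(a, a.copy(), n_bootstrap=400, seed=1)
        assert np.all(test.boot_differences == 0.0)
        assert test.p_a_later == 0.0  # strict > 0 rule
        assert test.p_b_later == 0.0

    def test_seed_determinism(self):
        a = self._curves(peak_idx=20, seed=4)
        b = self._curves(peak_idx=60, seed=5)
        t1 = cd.bootstrap_peak_latency_difference(a, b, n_bootstrap=300, seed=7)
        t2 = cd.bootstrap_peak_latency_difference(a, b, n_bootstrap=300, seed=7)
        np.testing.assert_array_equal(t1.boot_differences, t2.boot_differences)

    def test_flat_curve_flagged_and_tie_broken_early(self):
        flat = np.full((6, 20), 55.0)
        peaked = self._curves(peak_idx=10, n_participants=6, n_t=20, seed=6)
        with pytest.warns(RuntimeWarning, match="flat"):
            test = cd.bootstrap_peak_latency_difference(flat, peaked,
                                                        n_bootstrap=100, seed=0)
        assert test.flat_input
        assert test.peak_ms_a == 0.0  # earliest timepoint wins the tie

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError, match="share"):
            cd.bootstrap_peak_latency_difference(np.zeros((4, 10)) + 50,
                                                 np.zeros((4, 12)) + 50)

    def test_p_definition_is_fraction_of_qualifying_samples(self):
        a = self._curves(peak_idx=40, sd=8.0, seed=9)
        b = self._curves(peak_idx=50, sd=8.0, seed=10)
        test = cd.bootstrap_peak_latency_difference(a, b, n_bootstrap=500, seed=2)
        assert test.p_a_later == (test.boot_differences > 0).mean()
        assert 0.0 <= test.p_a_later <= 1.0


class TestNullSimulator:
    def test_mean_and_autocorrelation(self):
        x = cd.simulate_null_accuracies(200, 300, seed=0, sd=2.5, ar_coef=0.8)
        assert abs(x.mean() - 50.0) < 0.1
        d = x - x.mean()
        lag1 = np.mean(d[:, 1:] * d[:, :-1]) / np.mean(d**2)
        assert 0.7 < lag1 < 0.9

    def test_family_wise_error_controlled(self):
        """Fraction of null datasets with any significant cluster stays near alpha."""
        hits = 0
        n_datasets = 60
        for i in range(n_datasets):
            null = cd.simulate_null_accuracies(12, 80, seed=1000 + i)
            res = cd.cluster_permutation_test(null, n_permutations=500, seed=i)
            hits += res.significant_mask.any()
        # binomial 95% upper bound around alpha=0.05 for 60 draws
        assert hits / n_datasets <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_datasets)
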