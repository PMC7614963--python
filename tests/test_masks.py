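"""Sampling densities, mask draws, partitions and density estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selfrecon as sr
from selfrecon.masks import MaskStructure


class TestColumnDensity:
    def test_scaling_hits_target_acceleration(self):
        d = sr.build_column_density(64, 4.0, order=8, center_cols=10, height=1)
        assert d.prob[0].sum() == pytest.approx(16.0, abs=0.08)
        assert d.accel == pytest.approx(4.0, rel=5e-3)

    def test_full_sampling_at_unit_acceleration(self):
        d = sr.build_column_density(64, 1.0, center_cols=10, height=2)
        assert np.all(d.prob == 1.0)

    def test_cap_bounds_probability(self):
        d = sr.build_column_density(64, 4.0, cap_epsilon=1e-3, height=2)
        assert d.prob.max() == pytest.approx(1 - 1e-3)
        assert np.all(d.prob <= 1 - 1e-3 + 1e-12)

    def test_center_columns_fully_sampled(self):
        d = sr.build_column_density(64, 4.0, center_cols=10, height=1)
        assert np.all(d.prob[0, 27:37] == 1.0)

    def test_density_constant_within_columns(self, column_dist):
        assert np.allclose(column_dist.prob, column_dist.prob[:1, :])

    def test_infeasible_acceleration_raises(self):
        # 10 always-on centre columns bound the acceleration by 64/10
        with pytest.raises(ValueError, match="infeasible"):
            sr.build_column_density(64, 20.0, center_cols=10)
        with pytest.raises(ValueError):
            sr.build_column_density(64, 0.5)

    def test_center_wider_than_grid_raises(self):
        with pytest.raises(ValueError):
            sr.build_column_density(8, 2.0, center_cols=10)


class TestBernoulliDensity:
    def test_scaling_hits_target_acceleration(self):
        d = sr.build_bernoulli_density(64, 64, accel=8.0, center_size=10)
        assert d.prob.sum() == pytest.approx(512.0, abs=2.6)

    def test_high_frequency_growth_outside_center(self):
        d = sr.build_bernoulli_density(
            64, 64, accel=1.2, order=2, center_size=10, low_freq_high_prob=False
        )
        row = d.prob[32, 37:]  # rightward ray outside the central square
        assert np.all(np.diff(row) >= -1e-12)

    def test_uniform_limit(self):
        d = sr.build_bernoulli_density(64, 64, accel=2.0, order=0, center_size=0)
        assert np.allclose(d.prob, 0.5)


class TestSampleMask:
    def test_degenerate_densities(self):
        ones = sr.MaskDistribution(np.ones((4, 6)), MaskStructure.BERNOULLI_2D)
        zeros = sr.MaskDistribution(np.zeros((4, 6)), MaskStructure.BERNOULLI_2D)
        assert np.all(sr.sample_mask(ones, 0).indicator == 1)
        assert np.all(sr.sample_mask(zeros, 0).indicator == 0)

    def test_column_mask_constant_along_readout(self, column_dist):
        m = sr.sample_mask(column_dist, 42)
        assert np.all(m.indicator == m.indicator[:1, :])

    def test_reproducible_given_seed(self, column_dist):
        a = sr.sample_mask(column_dist, 5).indicator
        b = sr.sample_mask(column_dist, 5).indicator
        assert np.array_equal(a, b)

    def test_column_frequencies_match_density(self, column_dist):
        n = 10_000
        rng = np.random.default_rng(2024)
        counts = np.zeros(64)
        for _ in range(n):
            counts += sr.sample_mask(column_dist, rng).indicator[0]
        p = column_dist.prob[0]
        se = np.sqrt(np.maximum(p * (1 - p) / n, 1e-12))
        within = np.abs(counts / n - p) <= 3 * se
        assert within.mean() >= 0.99

    def test_empirical_acceleration_converges(self, column_dist):
        rng = np.random.default_rng(7)
        frac = np.mean(
            [sr.sample_mask(column_dist, rng).indicator.mean() for _ in range(10_000)]
        )
        assert 1.0 / frac == pytest.approx(column_dist.target_accel, rel=0.01)


class TestPartition:
    def test_set_algebra_example(self):
        omega = sr.Mask(np.array([[1, 1, 1, 0]]))
        lam = sr.Mask(np.array([[0, 1, 0, 1]]))
        p = sr.partition_sets(omega, lam)
        assert np.array_equal(p.A, [[True, False, True, False]])
        assert np.array_equal(p.B, [[False, True, False, False]])
        assert sr.partition_ratio(p) == 2.0

    def test_degenerate_partitions(self):
        omega = sr.Mask(np.ones((2, 3), dtype=int))
        p_full = sr.partition_sets(omega, sr.Mask(np.ones((2, 3), dtype=int)))
        assert not p_full.A.any() and np.array_equal(p_full.B, omega.indicator.astype(bool))
        assert sr.partition_ratio(p_full) == 0.0
        p_empty = sr.partition_sets(omega, sr.Mask(np.zeros((2, 3), dtype=int)))
        assert not p_empty.B.any()
        with pytest.raises(ZeroDivisionError):
            sr.partition_ratio(p_empty)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            sr.partition_sets(sr.Mask(np.ones((2, 2), dtype=int)), sr.Mask(np.ones((3, 3), dtype=int)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_invariants_hold_for_every_draw(self, seed):
        rng = np.random.default_rng(seed)
        dist = sr.MaskDistribution(rng.uniform(0, 1, (8, 8)), MaskStructure.BERNOULLI_2D)
        omega = sr.sample_mask(dist, seed)
        lam = sr.sample_mask(dist, seed + 1)
        p = sr.partition_sets(omega, lam)
        assert np.array_equal(p.A | p.B, omega.indicator.astype(bool))
        assert not np.any(p.A & p.B)

    def test_expected_ratio_for_uniform_half_masks(self):
        # E|A|/E|B| = (1-ptilde)/ptilde = 1 for p = ptilde = 0.5
        dist = sr.MaskDistribution(np.full((100, 100), 0.5), MaskStructure.BERNOULLI_2D)
        rng = np.random.default_rng(31)
        ratios = [
            sr.partition_ratio(
                sr.partition_sets(sr.sample_mask(dist, rng), sr.sample_mask(dist, rng))
            )
            for _ in range(100)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)


class TestEstimateDensity:
    def test_deterministic_sampler(self):
        sampler = lambda rng: sr.Mask(np.ones((4, 4), dtype=int))
        d = sr.estimate_density(sampler, 5, 0)
        assert np.all(d.prob == 1.0)

    def test_bernoulli_sampler_coverage(self):
        p = 0.3
        dist = sr.MaskDistribution(np.full((20, 20), p), MaskStructure.BERNOULLI_2D)
        d = sr.estimate_density(lambda rng: sr.sample_mask(dist, rng), 10_000, 99)
        se = np.sqrt(p * (1 - p) / 10_000)
        within = np.abs(d.prob - p) <= 3 * se
        assert within.mean() >= 0.98

    def test_zero_draws_raises(self):
        with pytest.raises(ValueError):
            sr.estimate_density(lambda rng: sr.Mask(np.ones((2, 2), dtype=int)), 0, 0)
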