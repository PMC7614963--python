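"""Synthetic phantoms, coil maps, k-space simulation and toy ensembles."""

import numpy as np
import pytest

import selfrecon as sr
from selfrecon._fft import fft2c, ifft2c
from selfrecon.synth import save_dataset


class TestPhantom:
    def test_deterministic_per_seed(self):
        a = sr.make_phantom(32, 32, rng_seed=3)
        b = sr.make_phantom(32, 32, rng_seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sr.make_phantom(32, 32, rng_seed=4))

    def test_background_only_without_ellipses(self):
        img = sr.make_phantom(32, 32, n_ellipses=0, rng_seed=0)
        # smooth background: small gradient everywhere
        assert np.max(np.abs(np.diff(np.abs(img), axis=0))) < 0.1

    def test_spectral_energy_concentrated_at_low_frequencies(self):
        # >= 90% of spectral energy inside the central half-band in each
        # dimension (a quarter of the grid area): the regime that makes
        # variable-density sampling appropriate
        for seed in range(5):
            img = sr.make_phantom(64, 64, rng_seed=seed)
            spec = np.abs(fft2c(img)) ** 2
            frac = spec[16:48, 16:48].sum() / spec.sum()
            assert frac >= 0.90


class TestCoils:
    def test_single_coil_has_unit_magnitude(self):
        s = sr.make_coils(1, 16, 16, rng_seed=0)
        assert np.allclose(np.abs(s), 1.0)

    def test_rss_normalisation(self):
        s = sr.make_coils(6, 24, 24, rng_seed=1)
        assert np.allclose(np.sum(np.abs(s) ** 2, axis=0), 1.0, atol=1e-10)

    def test_deterministic_per_seed(self):
        assert np.array_equal(sr.make_coils(3, 8, 8, 5), sr.make_coils(3, 8, 8, 5))


class TestForwardKspace:
    def test_parseval(self):
        img = sr.make_phantom(32, 32, rng_seed=2)
        coils = sr.make_coils(4, 32, 32, rng_seed=2)
        y0 = sr.forward_kspace(img, coils).array
        lhs = np.sum(np.abs(y0) ** 2)
        rhs = np.sum(np.abs(coils * img[None]) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_inverse_transform_recovers_coil_images(self):
        img = sr.make_phantom(16, 16, rng_seed=1)
        coils = sr.make_coils(2, 16, 16, rng_seed=1)
        y0 = sr.forward_kspace(img, coils).array
        assert np.allclose(ifft2c(y0), coils * img[None], atol=1e-10)

    def test_delta_image_gives_flat_spectrum(self):
        img = np.zeros((16, 16), dtype=complex)
        img[8, 8] = 1.0  # delta at the image-domain origin of the centred FFT
        flat_coil = np.ones((1, 16, 16), dtype=complex)
        y0 = sr.forward_kspace(img, flat_coil).array
        assert np.allclose(np.abs(y0), 1.0 / 16.0, atol=1e-12)


class TestDataset:
    def test_record_count_and_distinct_masks(self, small_dataset):
        assert len(small_dataset) == 6
        masks = [small_dataset.omega(i).indicator for i in range(6)]
        assert any(not np.array_equal(masks[0], m) for m in masks[1:])

    def test_ground_truth_locked_by_default(self, small_dataset):
        with pytest.raises(sr.GroundTruthError):
            small_dataset.ground_truth(0)
        with small_dataset.expose_ground_truth():
            y0 = small_dataset.ground_truth(0)
            assert y0.shape == (2, 64, 64)
        with pytest.raises(sr.GroundTruthError):
            small_dataset.ground_truth(0)

    def test_singly_subsampled_chain(self, small_dataset):
        with small_dataset.expose_ground_truth():
            y0 = small_dataset.ground_truth(1)
        y = small_dataset.y(1)
        m = small_dataset.omega(1).astype(float)
        assert np.array_equal(y, y0 * m)

    def test_regeneration_is_bit_identical(self, column_dist, tmp_path):
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        sr.make_dataset(1, 2, column_dist, rng_seed=5, n_coils=2, path=str(p1))
        sr.make_dataset(1, 2, column_dist, rng_seed=5, n_coils=2, path=str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_hdf5_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "ds.h5"
        save_dataset(small_dataset, str(path))
        loaded = sr.synth.load_dataset(str(path))
        assert len(loaded) == len(small_dataset)
        assert np.array_equal(loaded.y(0), small_dataset.y(0))
        with pytest.raises(sr.GroundTruthError):
            loaded.ground_truth(0)


class TestToyEnumeration:
    def test_outcome_count_and_total_probability(self):
        spec = sr.DiscreteToySpec(n=2, alphabet=[1.0], p=[0.5, 0.5], p_tilde=[0.5, 0.5])
        table = sr.enumerate_toy(spec)
        assert len(table.prob) == 16  # 1 data outcome x 4 masks x 4 masks
        assert table.prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_column_coupling_halves_mask_outcomes(self):
        spec = sr.DiscreteToySpec(
            n=4,
            alphabet=[1.0],
            p=[0.5] * 4,
            p_tilde=[0.5] * 4,
            columns=[0, 0, 1, 1],  # 2 columns of 2 rows
        )
        table = sr.enumerate_toy(spec)
        # 4 mask outcomes per mask instead of 16
        assert len(table.prob) == 16
        assert table.prob.sum() == pytest.approx(1.0, abs=1e-12)
        # rows within a column are fully coupled
        assert np.array_equal(table.omega[:, 0], table.omega[:, 1])
        assert np.array_equal(table.lam[:, 2], table.lam[:, 3])

    def test_conditional_membership_probability(self, toy_spec_uniform):
        # P(j in Omega | ytilde_j = 0) = p(1-pt) / (1 - p pt) = 1/3
        table = sr.enumerate_toy(toy_spec_uniform)
        yt = table.ytilde
        sel = yt[:, 0] == 0.0
        p_omega = table.prob[sel & table.omega[:, 0]].sum() / table.prob[sel].sum()
        assert p_omega == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_marginals_match_analytic_probabilities(self):
        spec = sr.DiscreteToySpec(n=3, alphabet=[1.0, 2.0], p=[0.2, 0.5, 0.9], p_tilde=[0.1, 0.4, 0.7])
        table = sr.enumerate_toy(spec)
        for j in range(3):
            assert table.prob[table.omega[:, j]].sum() == pytest.approx(spec.p[j], abs=1e-12)
            assert table.prob[table.lam[:, j]].sum() == pytest.approx(spec.p_tilde[j], abs=1e-12)

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError, match="exclude 0"):
            sr.DiscreteToySpec(n=1, alphabet=[0.0, 1.0], p=[0.5], p_tilde=[0.5])
        with pytest.raises(ValueError, match="p_j > 0|p_tilde"):
            sr.DiscreteToySpec(n=1, alphabet=[1.0], p=[0.0], p_tilde=[0.5])
        with pytest.raises(ValueError):
            sr.DiscreteToySpec(n=1, alphabet=[1.0], p=[0.5], p_tilde=[1.0])
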