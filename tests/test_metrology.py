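"""Metrology oracles: ROI noise, contrast, Hotelling template, s' index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kedgect.metrology import (ROISample, contrast, hotelling_template,
                               roi_noise, roi_stats, separability_index)
from kedgect.projector import AcquisitionProtocol
from kedgect.recon import ReconImage
from kedgect.spectrum import EnergyBin


def make_image(pixels, fov_cm=32.0):
    n = pixels.shape[0]
    prot = AcquisitionProtocol(n_views=4, n_channels=n, fov_cm=fov_cm, N0=1.0)
    return ReconImage(pixels, 10.0 * fov_cm / n, EnergyBin(20.0, 70.0), prot)


def closed_form_dprime(mean_a, mean_b, cov):
    """Population separability: Mahalanobis distance between class means."""
    d = np.asarray(mean_a, float) - np.asarray(mean_b, float)
    return float(np.sqrt(d @ np.linalg.solve(np.asarray(cov, float), d)))


class TestRoiNoise:
    def test_constant_image_has_zero_noise(self):
        img = make_image(np.full((64, 64), 3.0))
        assert roi_noise(img, (0, 0), 4.0) == 0.0

    def test_gaussian_field_recovers_sigma(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.normal(0.0, 10.0, size=(256, 256)), fov_cm=32.0)
        # ~10^4 voxels in a 7 cm ROI at 1.25 mm pixels
        assert roi_noise(img, (0, 0), 7.0) == pytest.approx(10.0, abs=0.3)

    def test_undersized_roi_rejected(self):
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            roi_noise(img, (0, 0), 0.4)

    def test_roi_outside_image_rejected(self):
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            roi_noise(img, (40.0, 40.0), 2.0)


class TestContrast:
    def test_identical_roi_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.normal(50.0, 5.0, size=(64, 64)))
        assert contrast(img, (0, 0), 2.0, (0, 0), 2.0) == 0.0

    def test_overlapping_rois_rejected(self):
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            contrast(img, (1.0, 0.0), 2.0, (0.0, 0.0), 2.0)

    def test_mean_difference(self):
        px = np.zeros((64, 64))
        img = make_image(px, fov_cm=32.0)
        from kedgect.recon import disk_mask

        m = disk_mask(64, 0.5, (8.0, 0.0), 2.0)
        px[m] = 120.0
        assert contrast(img, (8.0, 0.0), 1.5, (0, 0), 2.0) == pytest.approx(120.0)


class TestHotellingTemplate:
    def test_equal_means_give_zero_template(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 2))
        w = hotelling_template(ROISample(x), ROISample(x.copy()))
        assert np.allclose(w, 0.0)

    def test_identity_covariance_returns_mean_difference(self):
        rng = np.random.default_rng(3)
        n = 200000
        a = rng.normal([2.0, -1.0], 1.0, size=(n, 2))
        b = rng.normal([0.0, 0.0], 1.0, size=(n, 2))
        w = hotelling_template(ROISample(a), ROISample(b))
        assert np.allclose(w, [2.0, -1.0], atol=0.02)

    def test_matches_explicit_two_by_two_solve(self):
        rng = np.random.default_rng(4)
        cov = np.array([[4.0, 1.2], [1.2, 2.0]])
        l = np.linalg.cholesky(cov)
        a = rng.normal(size=(4000, 2)) @ l.T + [3.0, 1.0]
        b = rng.normal(size=(4000, 2)) @ l.T
        w = hotelling_template(ROISample(a), ROISample(b), ridge=0.0)
        s = 0.5 * (np.cov(a, rowvar=False) + np.cov(b, rowvar=False))
        det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        inv = np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det
        ref = inv @ (a.mean(axis=0) - b.mean(axis=0))
        assert np.allclose(w, ref, rtol=1e-10)

    def test_degenerate_covariance_surfaces_error(self):
        a = np.tile([1.0, 2.0], (50, 1))
        b = np.tile([0.0, 0.0], (50, 1))
        with pytest.raises(np.linalg.LinAlgError):
            hotelling_template(ROISample(a), ROISample(b), ridge=0.0)


class TestSeparabilityIndex:
    def test_null_case_is_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10000, 2))
        b = rng.normal(size=(10000, 2))
        assert separability_index(ROISample(a), ROISample(b)).s_prime < 0.2

    def test_known_gaussian_classes_reach_closed_form(self):
        rng = np.random.default_rng(6)
        n = 100000
        a = rng.normal([3.0, 4.0], 1.0, size=(n, 2))
        b = rng.normal([0.0, 0.0], 1.0, size=(n, 2))
        res = separability_index(ROISample(a), ROISample(b))
        assert res.s_prime == pytest.approx(5.0, abs=0.05)

    def test_closed_form_bias_below_two_percent(self):
        """On correlated Gaussian data, s' estimates the Mahalanobis
        distance with < 2% bias at n = 1e5."""
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        mean_a, mean_b = [1.5, -0.5], [0.0, 1.0]
        l = np.linalg.cholesky(cov)
        n = 100000
        a = rng.normal(size=(n, 2)) @ l.T + mean_a
        b = rng.normal(size=(n, 2)) @ l.T + mean_b
        ref = closed_form_dprime(mean_a, mean_b, cov)
        got = separability_index(ROISample(a), ROISample(b)).s_prime
        assert abs(got - ref) / ref < 0.02

    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(8)
        a = ROISample(rng.normal(1.0, 2.0, size=(300, 2)))
        b = ROISample(rng.normal(0.0, 1.0, size=(400, 2)))
        assert separability_index(a, b).s_prime == separability_index(b, a).s_prime

    def test_affine_invariance(self):
        """A common invertible channel transform leaves s' unchanged."""
        rng = np.random.default_rng(9)
        a = rng.normal([2.0, 0.0], [1.0, 2.0], size=(5000, 2))
        b = rng.normal([0.0, 1.0], [2.0, 1.0], size=(5000, 2))
        m = np.array([[1.3, -0.4], [0.7, 2.1]])
        s0 = separability_index(ROISample(a), ROISample(b), ridge=0.0).s_prime
        s1 = separability_index(ROISample(a @ m.T), ROISample(b @ m.T), ridge=0.0).s_prime
        assert s1 == pytest.approx(s0, rel=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_magnitude_and_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a = ROISample(rng.normal(rng.normal(size=2), 1.0, size=(200, 2)))
        b = ROISample(rng.normal(rng.normal(size=2), 1.0, size=(200, 2)))
        r_ab = separability_index(a, b)
        r_ba = separability_index(b, a)
        assert r_ab.s_prime >= 0.0
        assert r_ab.s_prime == pytest.approx(r_ba.s_prime, rel=1e-12)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            ROISample(np.array([[1.0, 2.0]]))


def test_roi_stats_shapes():
    rng = np.random.default_rng(10)
    s = roi_stats(ROISample(rng.normal(size=(100, 2)), "x"))
    assert s.mean_per_bin.shape == (2,) and s.std_per_bin.shape == (2,)
    assert s.n_voxels == 100 and np.all(s.std_per_bin >= 0)
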