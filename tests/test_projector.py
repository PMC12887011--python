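"""Forward-projection oracles: chords, Beer-Lambert composition, noise."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kedgect import attenuation as att
from kedgect.attenuation import SolutionMaterial
from kedgect.phantom import InsertSpec, PhantomSpec, build_water_cylinder
from kedgect.projector import (AcquisitionProtocol, chord_length,
                               expected_counts, segment_expected_counts,
                               simulate_sinogram, sweep_thresholds)
from kedgect.spectrum import EnergyBin, bin_fluence, make_spectrum

from conftest import mono_spectrum


def sampled_chord(center, radius, theta, s, n=200001):
    """Independent oracle: dense point-sampling of the ray inside the circle."""
    t = np.linspace(-30.0, 30.0, n)
    x = s * np.cos(theta) - t * np.sin(theta)
    y = s * np.sin(theta) + t * np.cos(theta)
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
    return inside.sum() * (t[1] - t[0])


class TestChordLength:
    def test_central_ray_is_diameter(self):
        assert chord_length((0, 0), 3.0, 0.3, 0.0) == pytest.approx(6.0)

    def test_tangent_and_disjoint_rays(self):
        assert chord_length((0, 0), 2.0, 0.0, 2.0) == pytest.approx(0.0)
        assert chord_length((0, 0), 2.0, 0.0, 5.0) == 0.0

    def test_offset_formula(self):
        assert chord_length((0, 0), 5.0, 0.0, 3.0) == pytest.approx(8.0)

    @pytest.mark.parametrize("center,radius,theta,s", [
        ((0.0, 0.0), 4.0, 0.0, 1.5),
        ((2.0, -1.0), 3.0, 0.7, 2.2),
        ((-5.0, 4.0), 1.25, 2.1, -4.0),
    ])
    def test_against_dense_sampling(self, center, radius, theta, s):
        ref = sampled_chord(center, radius, theta, s)
        assert chord_length(center, radius, theta, s) == pytest.approx(ref, abs=2e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(cx=st.floats(-8, 8), cy=st.floats(-8, 8), r=st.floats(0.1, 6),
           theta=st.floats(0, np.pi), s=st.floats(-12, 12))
    def test_bounded_by_diameter(self, cx, cy, r, theta, s):
        c = chord_length((cx, cy), r, theta, s)
        assert 0.0 <= c <= 2 * r + 1e-12


class TestExpectedCounts:
    def test_air_only_ray_sees_full_bin_fluence(self, spectrum_1e5):
        ph = build_water_cylinder(10.0)
        b = EnergyBin(50.0, 120.0)
        got = expected_counts(0.0, 14.0, ph, spectrum_1e5, b)
        assert got == pytest.approx(bin_fluence(spectrum_1e5, b), rel=1e-12)

    def test_monoenergetic_closed_form(self):
        ph = build_water_cylinder(15.0)
        sp = mono_spectrum(60.0, n0=1e6)
        dmu = att.water().linear_attenuation(60.5) - att.air().linear_attenuation(60.5)
        got = expected_counts(0.0, 0.0, ph, sp, EnergyBin(20.0, 120.0))
        assert got == pytest.approx(1e6 * np.exp(-dmu * 30.0), rel=1e-9)

    def test_two_bins_sum_to_full_range(self, spectrum_1e5):
        ph = PhantomSpec(15.0, (InsertSpec(
            (4.0, 0.0), 2.0, SolutionMaterial(att.get_element("Gd"), 4.0), "Gd"),))
        for t in sweep_thresholds():
            lo = expected_counts(0.1, 3.5, ph, spectrum_1e5, EnergyBin(20.0, t))
            hi = expected_counts(0.1, 3.5, ph, spectrum_1e5, EnergyBin(float(t), 120.0))
            full = expected_counts(0.1, 3.5, ph, spectrum_1e5, EnergyBin(20.0, 120.0))
            assert lo + hi == pytest.approx(full, rel=1e-9)


def test_segment_counts_match_single_ray_evaluation(spectrum_1e5):
    ph = PhantomSpec(15.0, (InsertSpec(
        (0.0, 5.0), 1.25, SolutionMaterial(att.get_element("I"), 4.0), "I"),))
    prot = AcquisitionProtocol(n_views=8, n_channels=16, fov_cm=36.0, N0=1e5)
    counts, air = segment_expected_counts(ph, spectrum_1e5, prot, [20.0, 70.0, 120.0])
    theta = prot.view_angles_rad[3]
    s = prot.channel_offsets_cm[9]
    ref_lo = expected_counts(theta, s, ph, spectrum_1e5, EnergyBin(20.0, 70.0))
    assert counts[3, 9, 0] == pytest.approx(ref_lo, rel=1e-10)
    assert air[1] == pytest.approx(bin_fluence(spectrum_1e5, EnergyBin(70.0, 120.0)), rel=1e-12)


class TestSimulateSinogram:
    def test_noise_free_air_scan_is_zero(self, spectrum_1e5):
        ph = PhantomSpec(15.0, tuple())
        empty = PhantomSpec(0.01, tuple())  # vanishing object ~ air scan
        prot = AcquisitionProtocol(n_views=4, n_channels=8, fov_cm=36.0, N0=1e5)
        sino = simulate_sinogram(empty, prot, spectrum_1e5, prot.low_bin, noise_free=True)
        assert np.allclose(sino.values[:, np.abs(prot.channel_offsets_cm) > 0.1], 0.0)
        del ph

    def test_same_seed_is_bitwise_identical(self, spectrum_1e5):
        ph = build_water_cylinder(15.0)
        prot = AcquisitionProtocol(n_views=6, n_channels=12, fov_cm=36.0,
                                   N0=1e5, seed=42)
        a = simulate_sinogram(ph, prot, spectrum_1e5, prot.high_bin)
        b = simulate_sinogram(ph, prot, spectrum_1e5, prot.high_bin)
        assert np.array_equal(a.values, b.values)

    def test_poisson_mean_converges_to_noise_free(self, spectrum_1e5):
        """Monte Carlo: the mean of K noisy sinograms approaches the
        noise-free one within 3 standard errors per ray."""
        ph = build_water_cylinder(12.0)
        prot = AcquisitionProtocol(n_views=2, n_channels=16, fov_cm=30.0, N0=2e4)
        ref = simulate_sinogram(ph, prot, spectrum_1e5, prot.low_bin, noise_free=True)
        rng = np.random.default_rng(7)
        k = 200
        stack = np.stack([
            simulate_sinogram(ph, prot, spectrum_1e5, prot.low_bin, rng=rng).values
            for _ in range(k)])
        se = stack.std(axis=0, ddof=1) / np.sqrt(k)
        assert np.all(np.abs(stack.mean(axis=0) - ref.values) <= 3.0 * se + 1e-9)

    def test_photon_starvation_warning(self, caplog):
        ph = build_water_cylinder(15.0)
        starved = make_spectrum(N0=50.0)
        prot = AcquisitionProtocol(n_views=4, n_channels=16, fov_cm=32.0,
                                   N0=50.0, seed=3)
        with caplog.at_level(logging.WARNING, logger="kedgect.projector"):
            simulate_sinogram(ph, prot, starved, prot.low_bin)
        assert any("photon starvation" in r.message for r in caplog.records)


def test_beam_hardening_direction(spectrum_1e5):
    """Polychromatic hardening: water mu inferred from the central-ray line
    integral is below the ray-free mu at the bin's mean energy (low bin)."""
    from kedgect.spectrum import mean_energy, Spectrum

    ph = build_water_cylinder(15.0)
    b = EnergyBin(20.0, 70.0)
    n = expected_counts(0.0, 0.0, ph, spectrum_1e5, b)
    p = -np.log(n / bin_fluence(spectrum_1e5, b))
    mu_eff = p / 30.0
    mask = (spectrum_1e5.energies_keV >= 20.0) & (spectrum_1e5.energies_keV < 70.0)
    sub = Spectrum(spectrum_1e5.energies_keV[mask], spectrum_1e5.fluence[mask], 120.0)
    mu_mean_e = att.water().linear_attenuation(mean_energy(sub))
    assert mu_eff < mu_mean_e


def test_protocol_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        AcquisitionProtocol(low_threshold_keV=60.0, high_threshold_keV=50.0)
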