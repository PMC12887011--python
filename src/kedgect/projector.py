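"""Polychromatic two-bin forward projection of analytic circle phantoms.

Geometry is 2-D parallel beam: ``n_views`` angles uniformly spanning 180
degrees, ``n_channels`` detector elements spanning ``fov_cm``. The ray at
angle ``theta`` and signed offset ``s`` is the line
``x*cos(theta) + y*sin(theta) = s``; intersection lengths with circles are
exact chords, so there is no voxelization error in the projections.

Attenuation composes by Beer-Lambert per energy bin of the incident
spectrum. The spectrum is defined as the air-scan fluence at the detector,
so materials enter through their linear attenuation *relative to air*
(background chord minus insert chords carries water, insert chords carry
solution-minus-water). Expected counts in a detector energy bin are

    N_bin = sum_E  N(E) * exp( - sum_regions dmu_region(E) * L_region )

Noisy acquisitions Poisson-sample these expected counts; sinogram values
are flat-field normalized log line integrals ``-ln(N / N_air)`` with zero
counts clamped to 0.5 before the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import attenuation
from .phantom import PhantomSpec
from .spectrum import EnergyBin, Spectrum, bin_fluence

__all__ = [
    "AcquisitionProtocol",
    "BinnedSinogram",
    "chord_length",
    "expected_counts",
    "simulate_sinogram",
    "segment_expected_counts",
    "sweep_thresholds",
]

logger = logging.getLogger(__name__)

SWEEP_THRESHOLDS_KEV = tuple(range(50, 95, 5))


def sweep_thresholds() -> tuple[int, ...]:
    """The studied upper-threshold settings: 50..90 keV in 5 keV steps."""
    return SWEEP_THRESHOLDS_KEV


@dataclass(frozen=True)
class AcquisitionProtocol:
    kV: float = 120.0
    low_threshold_keV: float = 20.0
    high_threshold_keV: float = 70.0
    n_views: int = 360
    n_channels: int = 729
    fov_cm: float = 36.0
    N0: float = 1e5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.low_threshold_keV < self.high_threshold_keV < self.kV):
            raise ValueError("need low_threshold < high_threshold < kV")

    @property
    def low_bin(self) -> EnergyBin:
        return EnergyBin(self.low_threshold_keV, self.high_threshold_keV)

    @property
    def high_bin(self) -> EnergyBin:
        return EnergyBin(self.high_threshold_keV, self.kV)

    @property
    def channel_offsets_cm(self) -> np.ndarray:
        # centered on channel n//2, matching scikit-image's rotation center
        pitch = self.fov_cm / self.n_channels
        return (np.arange(self.n_channels) - self.n_channels // 2) * pitch

    @property
    def view_angles_rad(self) -> np.ndarray:
        return np.arange(self.n_views) * np.pi / self.n_views

    def at_threshold(self, t_keV: float) -> "AcquisitionProtocol":
        return replace(self, high_threshold_keV=float(t_keV))


@dataclass(frozen=True)
class BinnedSinogram:
    """Log-normalized line integrals, shape (n_views, n_channels)."""

    values: np.ndarray
    bin: EnergyBin
    protocol: AcquisitionProtocol
    noise_free: bool


def chord_length(center_xy_cm, radius_cm, theta_rad, offset_cm):
    """Intersection length of ray(s) with a circle; 0 when disjoint.

    Vectorizes over ``theta_rad``/``offset_cm`` arrays of a common shape.
    """
    cx, cy = center_xy_cm
    d = np.abs(np.asarray(offset_cm) - (cx * np.cos(theta_rad) + cy * np.sin(theta_rad)))
    h2 = radius_cm**2 - d**2
    return 2.0 * np.sqrt(np.clip(h2, 0.0, None))


def _path_matrix(phantom: PhantomSpec, theta: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-ray region path lengths, shape (n_rays, 1 + n_inserts).

    Column 0 is the full background chord; insert columns are insert
    chords (material deltas are taken relative to water, so the background
    chord is not reduced by insert chords).
    """
    cols = [chord_length((0.0, 0.0), phantom.background_radius_cm, theta, s)]
    for ins in phantom.inserts:
        cols.append(chord_length(ins.center_xy_cm, ins.radius_cm, theta, s))
    return np.stack(cols, axis=-1)


def _delta_mu_matrix(phantom: PhantomSpec, energies_keV: np.ndarray) -> np.ndarray:
    """Linear attenuation deltas per region row: water-air, then each
    insert material minus water. Shape (1 + n_inserts, n_energies)."""
    mu_air = attenuation.air().linear_attenuation(energies_keV)
    mu_w = attenuation.water().linear_attenuation(energies_keV)
    rows = [mu_w - mu_air]
    for ins in phantom.inserts:
        rows.append(ins.material.linear_attenuation(energies_keV) - mu_w)
    return np.asarray(rows)


def segment_expected_counts(
    phantom: PhantomSpec,
    spectrum: Spectrum,
    protocol: AcquisitionProtocol,
    boundaries_keV,
    chunk_rays: int = 65536,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected detected counts per energy segment for every ray.

    ``boundaries_keV`` (e.g. ``[20, 50, 55, ..., 90, 120]``) splits the
    spectrum grid into contiguous segments; any threshold bin of the sweep
    is then a sum of segments, which lets one energy-resolved projection
    serve the whole threshold sweep.

    Returns ``(counts, air_counts)`` with shapes
    (n_views, n_channels, n_segments) and (n_segments,).
    """
    boundaries = np.asarray(boundaries_keV, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("segment boundaries must be strictly increasing")
    e = spectrum.energies_keV
    seg_idx = np.searchsorted(boundaries, e, side="right") - 1
    n_seg = len(boundaries) - 1
    valid = (seg_idx >= 0) & (seg_idx < n_seg)

    theta = np.repeat(protocol.view_angles_rad, protocol.n_channels)
    s = np.tile(protocol.channel_offsets_cm, protocol.n_views)
    n_rays = theta.size

    centers = spectrum.bin_centers_keV
    dmu = _delta_mu_matrix(phantom, centers)  # (regions, nE)
    fluence = np.where(valid, spectrum.fluence, 0.0)

    # per-segment one-hot weighting of the fluence: (nE, n_seg)
    seg_weight = np.zeros((e.size, n_seg))
    seg_weight[np.arange(e.size)[valid], seg_idx[valid]] = fluence[valid]

    counts = np.empty((n_rays, n_seg))
    for start in range(0, n_rays, chunk_rays):
        sl = slice(start, min(start + chunk_rays, n_rays))
        paths = _path_matrix(phantom, theta[sl], s[sl])  # (chunk, regions)
        trans = np.exp(-(paths @ dmu))  # (chunk, nE)
        counts[sl] = trans @ seg_weight
    air_counts = seg_weight.sum(axis=0)
    return counts.reshape(protocol.n_views, protocol.n_channels, n_seg), air_counts


def expected_counts(
    theta_rad: float,
    offset_cm: float,
    phantom: PhantomSpec,
    spectrum: Spectrum,
    bin: EnergyBin,
) -> float:
    """Expected detected photons in one bin for a single ray."""
    mask = (spectrum.energies_keV >= bin.lo_keV) & (spectrum.energies_keV < bin.hi_keV)
    centers = spectrum.bin_centers_keV[mask]
    dmu = _delta_mu_matrix(phantom, centers)
    paths = _path_matrix(phantom, np.asarray(theta_rad), np.asarray(offset_cm))
    return float(spectrum.fluence[mask] @ np.exp(-(paths @ dmu)))


def counts_to_sinogram(counts: np.ndarray, air_counts: float) -> tuple[np.ndarray, int]:
    """Flat-field normalize and log; returns (sinogram, n_clamped)."""
    clamped = counts < 0.5
    safe = np.where(clamped, 0.5, counts)
    return -np.log(safe / air_counts), int(np.count_nonzero(clamped & (counts <= 0)))


def sample_counts(expected: np.ndarray, rng: np.random.Generator,
                  normal_field: Optional[np.ndarray] = None) -> np.ndarray:
    """Poisson photon noise; optionally via a shared standard-normal field
    (Gaussian approximation with common random numbers across settings)."""
    if normal_field is None:
        return rng.poisson(expected).astype(float)
    k = np.rint(expected + np.sqrt(expected) * normal_field)
    return np.clip(k, 0.0, None)


def simulate_sinogram(
    phantom: PhantomSpec,
    protocol: AcquisitionProtocol,
    spectrum: Spectrum,
    bin: EnergyBin,
    noise_free: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> BinnedSinogram:
    """Simulate one binned sinogram; deterministic given protocol.seed."""
    counts, air = segment_expected_counts(
        phantom, spectrum, protocol, [bin.lo_keV, bin.hi_keV]
    )
    counts, air = counts[..., 0], float(air[0])
    if not noise_free:
        if rng is None:
            rng = np.random.default_rng(protocol.seed)
        counts = rng.poisson(counts).astype(float)
    values, n_clamped = counts_to_sinogram(counts, air)
    if n_clamped > 0.01 * values.size:
        logger.warning(
            "photon starvation: %d of %d rays recorded zero counts in bin %s",
            n_clamped, values.size, bin,
        )
    return BinnedSinogram(values, bin, protocol, noise_free)


def air_fluence(spectrum: Spectrum, bin: EnergyBin) -> float:
    """Air-scan (flat field) counts for a bin; alias for bin_fluence."""
    return bin_fluence(spectrum, bin)
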