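"""Filtered back projection, HU calibration and Gaussian denoising.

FBP uses the ramp (Ram-Lak) filter with linear interpolation via
scikit-image's ``iradon``. The detector channel pitch equals the recon
pixel pitch, so ``n_channels`` fixes the grid size; line integrals are
unitless and the output is converted to linear attenuation in 1/cm.

Hounsfield calibration follows the scanner's air/water correction: for
each energy bin and threshold setting, a noise-free scan of a plain water
cylinder under the identical protocol yields the bin-effective water
attenuation; air is the flat-field reference and reconstructs to zero, so

    HU = 1000 * (mu - mu_water_eff) / (mu_water_eff - mu_air_eff)

maps water to 0 HU and air to -1000 HU per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import iradon

from .phantom import PhantomSpec, build_water_cylinder, pixel_grid
from .projector import AcquisitionProtocol, BinnedSinogram, segment_expected_counts, counts_to_sinogram
from .spectrum import EnergyBin, Spectrum

__all__ = ["ReconImage", "fbp", "calibrate_hu", "denoise", "water_calibration",
           "reconstruct_mu", "disk_mask"]


@dataclass(frozen=True)
class ReconImage:
    """Square HU image with its acquisition context."""

    pixels: np.ndarray
    pixel_size_mm: float
    bin: EnergyBin
    protocol: AcquisitionProtocol

    @property
    def grid_n(self) -> int:
        return self.pixels.shape[0]


def fbp(sinogram: BinnedSinogram) -> np.ndarray:
    """Ramp-filtered back projection -> linear attenuation image (1/cm).

    The sinogram must be (n_views, n_channels) with channels spanning the
    protocol fov; the output grid is n_channels x n_channels with pixel
    pitch fov/n_channels.
    """
    prot = sinogram.protocol
    if sinogram.values.shape != (prot.n_views, prot.n_channels):
        raise ValueError("sinogram shape inconsistent with its protocol")
    theta_deg = np.degrees(prot.view_angles_rad)
    mu_px = iradon(
        sinogram.values.T,
        theta=theta_deg,
        filter_name="ramp",
        interpolation="linear",
        circle=True,
        output_size=prot.n_channels,
    )
    pixel_cm = prot.fov_cm / prot.n_channels
    return mu_px / pixel_cm


def calibrate_hu(
    mu_image: np.ndarray,
    bin: EnergyBin,
    protocol: AcquisitionProtocol,
    mu_water_eff: float,
    mu_air_eff: float = 0.0,
    pixel_size_mm: float | None = None,
) -> ReconImage:
    """Convert an attenuation image (1/cm) to Hounsfield units."""
    if mu_water_eff <= mu_air_eff:
        raise ValueError("degenerate calibration: water mu must exceed air mu")
    hu = 1000.0 * (mu_image - mu_water_eff) / (mu_water_eff - mu_air_eff)
    if pixel_size_mm is None:
        pixel_size_mm = 10.0 * protocol.fov_cm / protocol.n_channels
    return ReconImage(hu, pixel_size_mm, bin, protocol)


def denoise(image: ReconImage, sigma_px: float = 1.0) -> ReconImage:
    """2-D Gaussian smoothing (single-slice analog of volumetric filtering)."""
    if sigma_px < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_px == 0:
        return image
    return ReconImage(gaussian_filter(image.pixels, sigma_px),
                      image.pixel_size_mm, image.bin, image.protocol)


def water_linearizer(spectrum: Spectrum, bin: EnergyBin,
                     max_path_cm: float = 45.0, n_nodes: int = 128):
    """Water beam-hardening correction for one energy bin.

    Returns ``(correct, mu_ref)``: ``correct`` maps a polychromatic log
    sinogram to the monoenergetic water-equivalent line integral
    ``mu_ref * L`` (L the water path in cm), by inverting the analytic
    polychromatic water response of the bin; ``mu_ref`` is the
    fluence-weighted bin-effective water attenuation. Rays through pure
    water then reconstruct to a flat ``mu_ref`` with no cupping; this is
    the standard first-order water correction of clinical CT.
    """
    from . import attenuation

    mask = (spectrum.energies_keV >= bin.lo_keV) & (spectrum.energies_keV < bin.hi_keV)
    centers = spectrum.bin_centers_keV[mask]
    w = spectrum.fluence[mask]
    if w.sum() <= 0:
        raise ValueError("bin holds no fluence")
    dmu = (attenuation.water().linear_attenuation(centers)
           - attenuation.air().linear_attenuation(centers))
    mu_ref = float(np.average(dmu, weights=w))
    lengths = np.linspace(0.0, max_path_cm, n_nodes)
    p_poly = -np.log((w[np.newaxis, :] * np.exp(-np.outer(lengths, dmu))).sum(axis=1)
                     / w.sum())

    def correct(p: np.ndarray) -> np.ndarray:
        # monotone response: invert by interpolation, linear beyond the table
        slope_end = (lengths[-1] - lengths[-2]) / (p_poly[-1] - p_poly[-2])
        length = np.interp(p, p_poly, lengths)
        length = np.where(p > p_poly[-1],
                          lengths[-1] + (p - p_poly[-1]) * slope_end, length)
        length = np.where(p < 0, p / p_poly[1] * lengths[1], length)
        return mu_ref * length

    return correct, mu_ref


def disk_mask(grid_n: int, pixel_size_cm: float, center_xy_cm, radius_cm) -> np.ndarray:
    """Boolean mask of a circular ROI on the recon grid."""
    x, y = pixel_grid(grid_n, pixel_size_cm)
    cx, cy = center_xy_cm
    return (x - cx) ** 2 + (y - cy) ** 2 <= radius_cm**2


def reconstruct_mu(values: np.ndarray, bin: EnergyBin,
                   protocol: AcquisitionProtocol) -> np.ndarray:
    """FBP convenience for raw sinogram arrays."""
    return fbp(BinnedSinogram(values, bin, protocol, noise_free=True))


def water_calibration(
    protocol: AcquisitionProtocol,
    spectrum: Spectrum,
    bin: EnergyBin,
    roi_radius_cm: float = 2.0,
    phantom: PhantomSpec | None = None,
) -> float:
    """Bin-effective water attenuation (1/cm) from a noise-free scan of a
    plain water cylinder, measured in a central ROI of the reconstruction."""
    if phantom is None:
        phantom = build_water_cylinder()
    counts, air = segment_expected_counts(phantom, spectrum, protocol,
                                          [bin.lo_keV, bin.hi_keV])
    values, _ = counts_to_sinogram(counts[..., 0], float(air[0]))
    mu = fbp(BinnedSinogram(values, bin, protocol, noise_free=True))
    pixel_cm = protocol.fov_cm / protocol.n_channels
    roi = disk_mask(protocol.n_channels, pixel_cm, (0.0, 0.0), roi_radius_cm)
    return float(mu[roi].mean())
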