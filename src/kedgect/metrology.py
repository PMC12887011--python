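"""ROI metrics and the Hotelling-observer separability index.

Noise is the sample standard deviation of HU values in a water-background
ROI; contrast is the ROI-mean difference between an insert and the water
background, per energy-bin image.

Separability between two materials uses per-voxel multi-bin HU vectors
(here 2-D: low-bin HU, high-bin HU) drawn from spatially matched ROI
masks. The linear Hotelling observer template is

    w = S^-1 (mean_A - mean_B),     S = (Sigma_A + Sigma_B) / 2

(sample covariances, with a small trace-scaled ridge for conditioning).
Projecting every voxel vector onto w gives per-class test statistics
lambda, and the separability index is the standardized difference

    s' = (mean lambda_A - mean lambda_B)
         / sqrt( (var lambda_A + var lambda_B) / 2 )

reported as a magnitude (the sign only encodes which class is "A"). For
multivariate Gaussian classes s' estimates the Mahalanobis distance
sqrt(dmu' S^-1 dmu), which the tests use as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import ReconImage, disk_mask

__all__ = ["ROISample", "ROIStats", "SeparabilityResult", "roi_noise",
           "contrast", "roi_stats", "hotelling_template",
           "separability_index", "extract_roi_vectors"]

DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class ROISample:
    """Per-voxel multi-bin HU vectors (n_voxels, n_bins) from one ROI."""

    vectors: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if v.shape[0] < 2:
            raise ValueError("an ROI sample needs at least 2 voxels")
        object.__setattr__(self, "vectors", v)

    @property
    def n_voxels(self) -> int:
        return self.vectors.shape[0]

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class ROIStats:
    mean_per_bin: np.ndarray
    std_per_bin: np.ndarray
    n_voxels: int


@dataclass(frozen=True)
class SeparabilityResult:
    template_w: np.ndarray
    lambda_mean_A: float
    lambda_mean_B: float
    lambda_var_A: float
    lambda_var_B: float
    s_prime: float  # magnitude
    sign: int


def roi_stats(sample: ROISample) -> ROIStats:
    return ROIStats(sample.vectors.mean(axis=0),
                    sample.vectors.std(axis=0, ddof=1),
                    sample.n_voxels)


def _roi_values(image: ReconImage, center_xy_cm, radius_cm) -> np.ndarray:
    px_cm = image.pixel_size_mm / 10.0
    mask = disk_mask(image.grid_n, px_cm, center_xy_cm, radius_cm)
    if not mask.any():
        raise ValueError("ROI lies outside the image")
    return image.pixels[mask]


def roi_noise(image: ReconImage, center_xy_cm=(0.0, 0.0), radius_cm: float = 2.0) -> float:
    """Sample standard deviation of HU in a circular ROI (>= 25 voxels)."""
    vals = _roi_values(image, center_xy_cm, radius_cm)
    if vals.size < 25:
        raise ValueError(f"ROI too small for a noise estimate ({vals.size} voxels)")
    return float(vals.std(ddof=1))


def contrast(image: ReconImage, insert_center_xy_cm, insert_radius_cm,
             background_center_xy_cm=(0.0, 0.0), background_radius_cm: float = 2.0) -> float:
    """Mean insert HU minus mean background HU for one bin image."""
    d = np.hypot(insert_center_xy_cm[0] - background_center_xy_cm[0],
                 insert_center_xy_cm[1] - background_center_xy_cm[1])
    if 0 < d < insert_radius_cm + background_radius_cm:
        raise ValueError("insert and background ROIs overlap")
    ins = _roi_values(image, insert_center_xy_cm, insert_radius_cm)
    if d == 0:
        return 0.0
    bg = _roi_values(image, background_center_xy_cm, background_radius_cm)
    return float(ins.mean() - bg.mean())


def extract_roi_vectors(images: list[ReconImage], center_xy_cm, radius_cm,
                        label: str = "") -> ROISample:
    """Stack matched per-voxel values across bin images into an ROISample."""
    cols = [_roi_values(img, center_xy_cm, radius_cm) for img in images]
    if len({c.size for c in cols}) != 1:
        raise ValueError("bin images have mismatched grids")
    return ROISample(np.stack(cols, axis=1), label)


def _pooled_covariance(a: np.ndarray, b: np.ndarray, ridge: float) -> np.ndarray:
    d = a.shape[1]
    s = 0.5 * (np.cov(a, rowvar=False) + np.cov(b, rowvar=False))
    s = np.atleast_2d(s)
    return s + ridge * np.trace(s) / d * np.eye(d)


def hotelling_template(A: ROISample, B: ROISample, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Hotelling observer weights w = S^-1 (mean_A - mean_B).

    A singular pooled covariance (even after the ridge) raises
    ``numpy.linalg.LinAlgError`` rather than being silently zeroed.
    """
    if A.dimension != B.dimension:
        raise ValueError("samples must share the bin dimension")
    s = _pooled_covariance(A.vectors, B.vectors, ridge)
    delta = A.vectors.mean(axis=0) - B.vectors.mean(axis=0)
    cond = np.linalg.cond(s)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("pooled ROI covariance is degenerate")
    return np.linalg.solve(s, delta)


def separability_index(A: ROISample, B: ROISample, ridge: float = DEFAULT_RIDGE) -> SeparabilityResult:
    """Separability index s' between two ROI samples (magnitude + sign)."""
    w = hotelling_template(A, B, ridge)
    lam_a = A.vectors @ w
    lam_b = B.vectors @ w
    ma, mb = float(lam_a.mean()), float(lam_b.mean())
    va, vb = float(lam_a.var(ddof=1)), float(lam_b.var(ddof=1))
    denom = np.sqrt(0.5 * (va + vb))
    raw = (ma - mb) / denom if denom > 0 else np.inf
    return SeparabilityResult(w, ma, mb, va, vb, abs(float(raw)),
                              int(np.sign(raw)) or 1)
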