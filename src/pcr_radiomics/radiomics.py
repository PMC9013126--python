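"""Laplacian-of-Gaussian filtering and first-order ROI features.

The pCR model uses two first-order features computed on LoG-filtered
T2-weighted images: skewness of the ROI intensities after a sigma = 0.485 mm
filter and Shannon entropy of the binned ROI histogram after a
sigma = 0.344 mm filter.  Kernel widths are physical lengths and are
converted to voxel units per axis through the grid spacing.

Filtering defaults to in-plane 2-D (each axial slice filtered with sigma
converted via dx, dy only): staging rectal T2 images are 2-D acquisitions
whose slice thickness is an order of magnitude larger than the in-plane
pixel, so a sub-millimetre sigma along the slice axis would be
under-resolved.  A full 3-D mode is available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateDistributionError, EmptyROIError, SmallROIError
from .imaging_io import ImageVolume, ROIMask, check_aligned

FILTER_MODES = ("in-plane-2d", "3d")

#: ROIs below this voxel count give unstable moments/histograms.
MIN_ROI_VOXELS = 10


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings.

    ``sigma_entropy_mm`` / ``sigma_skewness_mm`` are the LoG kernel widths
    (mm) used for the entropy and skewness covariates respectively;
    ``n_bins`` is the fixed bin number for the entropy histogram (equal-width
    bins over the ROI min-max of the filtered response, log base 2).
    """

    sigma_entropy_mm: float = 0.344
    sigma_skewness_mm: float = 0.485
    n_bins: int = 64
    filter_mode: str = "in-plane-2d"
    min_roi_voxels: int = MIN_ROI_VOXELS

    def __post_init__(self):
        if self.sigma_entropy_mm <= 0 or self.sigma_skewness_mm <= 0:
            raise ValueError("LoG kernel widths must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.filter_mode not in FILTER_MODES:
            raise ValueError(f"filter_mode must be one of {FILTER_MODES}")

    def to_dict(self) -> dict:
        return {
            "sigma_entropy_mm": self.sigma_entropy_mm,
            "sigma_skewness_mm": self.sigma_skewness_mm,
            "n_bins": self.n_bins,
            "filter_mode": self.filter_mode,
            "min_roi_voxels": self.min_roi_voxels,
        }


@dataclass(frozen=True)
class FeatureVector:
    """The two model covariates extracted from one ROI."""

    skewness: float
    entropy: float
    roi_voxel_count: int


def _gaussian_kernel_1d(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian (order 0) or its second derivative (order 2).

    The smoothing kernel is normalised to unit sum; the derivative kernel is
    DC-corrected to exact zero sum so a constant input always yields a zero
    response, even at sub-voxel sigma where plain sampling leaves a bias.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    kernel = phi * (x**2 - sigma**2) / sigma**4
    return kernel - kernel.mean()


def log_filter(volume: ImageVolume, sigma_mm: float, mode: str = "in-plane-2d") -> ImageVolume:
    """Scale-normalised Laplacian-of-Gaussian response, sigma in millimetres.

    Computes ``sigma^2 * laplacian(G_sigma * I)`` with the Laplacian taken in
    physical coordinates; sigma is converted to voxel units per axis via the
    spacing.  In ``in-plane-2d`` mode only the x/y second derivatives enter
    and slices are filtered independently.  Reflect padding at edges; the
    output grid equals the input grid.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if mode not in FILTER_MODES:
        raise ValueError(f"mode must be one of {FILTER_MODES}")
    dx, dy, dz = volume.spacing
    axes = (0, 1) if mode == "in-plane-2d" else (0, 1, 2)
    spac = (dx, dy, dz)
    if sigma_mm < 0.1 * min(spac[a] for a in axes):
        warnings.warn(
            f"sigma {sigma_mm} mm is below 0.1x the finest spacing; "
            "the LoG filter is under-resolved",
            stacklevel=2,
        )
    vox = volume.voxels.astype(np.float64, copy=False)
    resp = np.zeros_like(vox)
    for deriv_axis in axes:
        term = vox
        for a in axes:
            kernel = _gaussian_kernel_1d(sigma_mm / spac[a], order=2 if a == deriv_axis else 0)
            term = ndimage.correlate1d(term, kernel, axis=a, mode="reflect")
        # second derivative wrt voxel index -> physical via 1/spacing^2
        resp += term / spac[deriv_axis] ** 2
    resp *= sigma_mm**2
    return ImageVolume(voxels=resp, spacing=volume.spacing, meta=dict(volume.meta))


def roi_intensities(volume: ImageVolume, mask: ROIMask) -> np.ndarray:
    """Voxel values under the mask in deterministic raster (C) order."""
    check_aligned(volume, mask)
    if mask.n_foreground == 0:
        raise EmptyROIError("mask has no foreground voxels")
    return volume.voxels[mask.voxels]


def skewness(values) -> float:
    """Population skewness m3 / m2^(3/2); no bias correction.

    Raises :class:`DegenerateDistributionError` on zero variance rather than
    silently returning 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise DegenerateDistributionError("skewness needs at least 2 values")
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    if m2 == 0.0:
        raise DegenerateDistributionError("zero variance: skewness undefined")
    m3 = np.mean((v - m) ** 3)
    return float(m3 / m2**1.5)


def entropy(values, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the equal-width-binned histogram.

    Bins span ``[min(values), max(values)]``; empty bins contribute 0.  A
    constant sample occupies a single bin and has entropy 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise EmptyROIError("entropy needs at least one value")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log2(p)))


def compute_signature_features(
    volume: ImageVolume, mask: ROIMask, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """Extract the model's two covariates from one volume/ROI pair.

    Entropy is computed on the LoG response at ``cfg.sigma_entropy_mm`` and
    skewness on an independent LoG response at ``cfg.sigma_skewness_mm``,
    both restricted to the ROI.
    """
    cfg = cfg or FeatureConfig()
    check_aligned(volume, mask)
    if mask.n_foreground == 0:
        raise EmptyROIError("mask has no foreground voxels")
    if mask.n_foreground < cfg.min_roi_voxels:
        raise SmallROIError(
            f"ROI has {mask.n_foreground} voxels, below the minimum {cfg.min_roi_voxels}"
        )
    resp_entropy = log_filter(volume, cfg.sigma_entropy_mm, cfg.filter_mode)
    resp_skew = log_filter(volume, cfg.sigma_skewness_mm, cfg.filter_mode)
    ent = entropy(roi_intensities(resp_entropy, mask), cfg.n_bins)
    skw = skewness(roi_intensities(resp_skew, mask))
    return FeatureVector(skewness=skw, entropy=ent, roi_voxel_count=mask.n_foreground)
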