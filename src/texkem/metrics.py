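"""Image-quality metrics for reconstruction evaluation.

Conventions: ``T`` is the reconstructed image, ``R`` the true (reference)
image.

* SNR (dB) = 10·log10( Σ T² / Σ (T−R)² )  — the reconstructed image's energy
  over the error energy (a reference-energy variant is available by flag).
* NMSE = Σ (T−R)² / Σ T².
* SSIM — the single-window (global) structural similarity
  (2·T̄·R̄ + c1)(2·σ_TR + c2) / ((T̄² + R̄² + c1)(σ_T² + σ_R² + c2)) with
  c1 = (k1·L)², c2 = (k2·L)², k1 = 0.01, k2 = 0.03, L the dynamic range.
  Identical images give exactly 1.
* SD = (1/R̄)·sqrt( Σ_mask (T−R)² / (n−1) ) over an ROI mask — a normalized
  root-mean-square deviation from the truth inside the region (an
  across-realizations background SD is also provided as ``ensemble_sd``).
* CRC = (T̄_ROI/T̄_BGD − 1) / (R̄_ROI/R̄_BGD − 1) — reconstructed ROI contrast
  over true ROI contrast; 1 means contrast is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ROISet",
    "MetricsReport",
    "snr",
    "nmse",
    "ssim",
    "roi_sd",
    "ensemble_sd",
    "crc",
    "line_profile",
    "rois_from_masks",
    "evaluate",
]

K1_DEFAULT = 0.01
K2_DEFAULT = 0.03


@dataclass
class ROISet:
    """Masks used for regional metrics: the tumor ROI, the contrast
    background (white matter excluding a safety margin around the tumor) and
    the white-matter noise region."""

    tumor: np.ndarray
    background: np.ndarray
    white_matter: np.ndarray

    def __post_init__(self):
        if np.any(self.tumor & self.background):
            raise ValueError("tumor and background ROIs must be disjoint")


@dataclass
class MetricsReport:
    snr: float
    nmse: float
    ssim: float
    sd: float
    crc: float


def _pair(T, R):
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    if T.shape != R.shape:
        raise ValueError(f"image shapes differ: {T.shape} vs {R.shape}")
    return T, R


def snr(T, R, reference: str = "reconstructed") -> float:
    """Signal-to-noise ratio in dB; errors on identical images (infinite)."""
    T, R = _pair(T, R)
    err = ((T - R) ** 2).sum()
    if err == 0:
        raise ValueError("images are identical: SNR is infinite")
    num = (T**2).sum() if reference == "reconstructed" else (R**2).sum()
    return float(10.0 * np.log10(num / err))


def nmse(T, R) -> float:
    """Normalized mean squared error Σ(T−R)²/ΣT²."""
    T, R = _pair(T, R)
    denom = (T**2).sum()
    if denom == 0:
        raise ValueError("reconstructed image is identically zero")
    return float(((T - R) ** 2).sum() / denom)


def ssim(T, R, k1: float = K1_DEFAULT, k2: float = K2_DEFAULT, L: float | None = None) -> float:
    """Global single-window SSIM; exactly 1 for identical images."""
    T, R = _pair(T, R)
    if L is None:
        L = float(max(T.max(), R.max()) - min(T.min(), R.min()))
        if L == 0:
            L = 1.0
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mt, mr = T.mean(), R.mean()
    vt, vr = T.var(), R.var()
    cov = ((T - mt) * (R - mr)).mean()
    return float(
        ((2 * mt * mr + c1) * (2 * cov + c2)) / ((mt**2 + mr**2 + c1) * (vt + vr + c2))
    )


def roi_sd(T, R, mask) -> float:
    """Normalized RMS deviation (1/R̄)·sqrt(Σ_mask(T−R)²/(n−1))."""
    T, R = _pair(T, R)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("ROI mask must contain at least 2 pixels")
    rbar = R[mask].mean()
    if rbar == 0:
        raise ValueError("true-image ROI mean is zero")
    diff2 = ((T[mask] - R[mask]) ** 2).sum()
    return float(np.sqrt(diff2 / (n - 1)) / rbar)


def ensemble_sd(recons: np.ndarray, mask, reference_mean: float | None = None) -> float:
    """Across-realizations pixel SD in a region, normalized by the mean.

    ``recons`` has shape (n_realizations, H, W).  This is the conventional
    background-variability reading of "SD"; :func:`roi_sd` is the primary
    definition.
    """
    recons = np.asarray(recons, dtype=float)
    if recons.ndim != 3 or recons.shape[0] < 2:
        raise ValueError("need a stack of at least 2 realizations")
    mask = np.asarray(mask, dtype=bool)
    sd_map = recons.std(axis=0, ddof=1)
    norm = reference_mean if reference_mean is not None else recons.mean(axis=0)[mask].mean()
    return float(sd_map[mask].mean() / norm)


def crc(T, R, roi_mask, bgd_mask) -> float:
    """Contrast recovery coefficient (recon ROI contrast / true ROI contrast)."""
    T, R = _pair(T, R)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    bgd_mask = np.asarray(bgd_mask, dtype=bool)
    if not roi_mask.any() or not bgd_mask.any():
        raise ValueError("ROI and background masks must be nonempty")
    r_contrast = R[roi_mask].mean() / R[bgd_mask].mean() - 1.0
    if r_contrast == 0:
        raise ValueError("true image has no ROI/background contrast")
    t_contrast = T[roi_mask].mean() / T[bgd_mask].mean() - 1.0
    return float(t_contrast / r_contrast)


def line_profile(image, p0, p1, n_samples: int = 200) -> np.ndarray:
    """Bilinearly interpolated intensities along the segment p0→p1
    ((row, col) endpoints, inclusive, evenly sampled)."""
    image = np.asarray(image, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError(f"endpoint {p} outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    return ndimage.map_coordinates(image, np.vstack([rows, cols]), order=1, mode="nearest")


def rois_from_masks(masks: dict[str, np.ndarray], margin: int = 2) -> ROISet:
    """Phantom ROI convention: tumor mask as ROI; white matter excluding a
    ``margin``-pixel dilation of the tumor as both CRC background and noise
    region."""
    tumor = masks["tumor"]
    wm = masks["white_matter"]
    guard = ndimage.binary_dilation(tumor, iterations=margin) if margin > 0 else tumor
    bgd = wm & ~guard
    return ROISet(tumor=tumor, background=bgd, white_matter=bgd)


def evaluate(T, R, rois: ROISet, L: float | None = None) -> MetricsReport:
    """All five metrics of one reconstructed frame against the truth."""
    return MetricsReport(
        snr=snr(T, R),
        nmse=nmse(T, R),
        ssim=ssim(T, R, L=L),
        sd=roi_sd(T, R, rois.white_matter),
        crc=crc(T, R, rois.tumor, rois.background),
    )
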