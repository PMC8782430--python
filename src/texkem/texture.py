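"""GGCM and GLRLM texture descriptors computed per pixel over sliding windows.

Two descriptors drive the texture-guided kernel:

* **IDM** — the inverse difference moment of the gray level-gradient
  cooccurrence matrix (GGCM).  A window is quantized to ``n_gray`` levels
  (``level = INT(value * N / max) + 1``, clamped to [1, N]); its Sobel
  gradient magnitude is quantized the same way to ``n_gradient`` levels; the
  GGCM is the joint histogram of (gray level, gradient level); and
  ``IDM = Σ_ij P(i,j) / (1 + (i−j)²)`` with P the normalized matrix.  IDM is
  in (0, 1] and equals 1 only when all mass sits on the diagonal — high for
  homogeneous texture.

* **LRLGE** — long-run low gray-level emphasis of the gray-level run length
  matrix (GLRLM).  Runs are *maximal* streaks of equal quantized level along a
  direction θ ∈ {0°, 45°, 90°, 135°} at unit step; ``p(i, j)`` counts runs of
  level i and length j, and ``LRLGE = (1/n_r) Σ_ij p(i,j)·j²/i²`` with
  ``n_r = Σ p``.  The per-pixel feature is the mean over the four directions.

A standard GLCM (gray-level cooccurrence) Haralick correlation is also
provided as the comparator feature used by intensity+GLCM kernel methods.

Quantization maxima (f_M, g_M) are window-local by default; windows with a
zero maximum map every pixel to level 1.  Image borders are handled by
replicate padding.  All sliding-window maps are numba-compiled; the public
per-patch functions call the same compiled cores, so there is exactly one
implementation of each definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "QuantizedImage",
    "GradientImage",
    "GrayGradientCooccurrence",
    "quantize_gray",
    "sobel_gradient",
    "ggcm",
    "idm",
    "glrlm",
    "lrlge",
    "lrlge_mean",
    "glcm_correlation",
    "feature_image",
    "DIRECTIONS",
]

DEFAULT_N_GRAY = 8
DEFAULT_N_GRADIENT = 8

# direction angle -> (row step, col step); 0 deg scans along rows rightward
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_DESCRIPTOR_CODES = {"idm": 0, "lrlge": 1, "glcm_correlation": 2}
_DEFAULT_WINDOWS = {"idm": 5, "lrlge": 3, "glcm_correlation": 5}


# ---------------------------------------------------------------------------
# numba cores (single source of truth for every definition)
# ---------------------------------------------------------------------------

@njit
def _quantize_core(patch, n_levels):
    """level = INT(value * N / max) + 1, clamped to [1, N]; all 1 if max <= 0."""
    out = np.empty(patch.shape, np.int64)
    fm = patch.max()
    if fm <= 0.0:
        out[:] = 1
        return out
    h, w = patch.shape
    for i in range(h):
        for j in range(w):
            lev = int(patch[i, j] * n_levels / fm) + 1
            if lev < 1:
                lev = 1
            elif lev > n_levels:
                lev = n_levels
            out[i, j] = lev
    return out


@njit
def _replicate_pad(img, pad):
    h, w = img.shape
    out = np.empty((h + 2 * pad, w + 2 * pad), img.dtype)
    for i in range(h + 2 * pad):
        si = min(max(i - pad, 0), h - 1)
        for j in range(w + 2 * pad):
            sj = min(max(j - pad, 0), w - 1)
            out[i, j] = img[si, sj]
    return out


@njit
def _sobel_core(patch):
    """Sobel gradient magnitude with replicate padding of the patch."""
    h, w = patch.shape
    p = _replicate_pad(patch, 1)
    g = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            ii = i + 1
            jj = j + 1
            gx = (
                p[ii + 1, jj - 1] + 2.0 * p[ii + 1, jj] + p[ii + 1, jj + 1]
                - p[ii - 1, jj - 1] - 2.0 * p[ii - 1, jj] - p[ii - 1, jj + 1]
            )
            gy = (
                p[ii - 1, jj + 1] + 2.0 * p[ii, jj + 1] + p[ii + 1, jj + 1]
                - p[ii - 1, jj - 1] - 2.0 * p[ii, jj - 1] - p[ii + 1, jj - 1]
            )
            g[i, j] = np.sqrt(gx * gx + gy * gy)
    return g


@njit
def _ggcm_core(F, G, n_gray, n_gradient):
    H = np.zeros((n_gray, n_gradient), np.int64)
    h, w = F.shape
    for i in range(h):
        for j in range(w):
            H[F[i, j] - 1, G[i, j] - 1] += 1
    return H


@njit
def _idm_from_H(H):
    tot = H.sum()
    acc = 0.0
    for i in range(H.shape[0]):
        for j in range(H.shape[1]):
            if H[i, j] > 0:
                d = i - j
                acc += H[i, j] / (1.0 + d * d)
    return acc / tot


@njit
def _idm_patch(patch, n_gray, n_gradient):
    F = _quantize_core(patch, n_gray)
    g = _sobel_core(patch)
    G = _quantize_core(g, n_gradient)
    H = _ggcm_core(F, G, n_gray, n_gradient)
    return _idm_from_H(H)


@njit
def _glrlm_core(q, n_levels, n_length, di, dj):
    """Count maximal runs of equal level along direction (di, dj)."""
    h, w = q.shape
    p = np.zeros((n_levels, n_length), np.int64)
    for i in range(h):
        for j in range(w):
            pi = i - di
            pj = j - dj
            # run starts where the previous cell is out of bounds or differs
            if 0 <= pi < h and 0 <= pj < w and q[pi, pj] == q[i, j]:
                continue
            length = 1
            ci = i + di
            cj = j + dj
            while 0 <= ci < h and 0 <= cj < w and q[ci, cj] == q[i, j]:
                length += 1
                ci += di
                cj += dj
            if length > n_length:
                length = n_length
            p[q[i, j] - 1, length - 1] += 1
    return p


@njit
def _lrlge_from_p(p):
    nr = p.sum()
    acc = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                acc += p[i, j] * ((j + 1.0) * (j + 1.0)) / ((i + 1.0) * (i + 1.0))
    return acc / nr


@njit
def _lrlge_from_q(q, n_levels):
    n_length = max(q.shape[0], q.shape[1])
    acc = 0.0
    dirs = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    for d in range(4):
        p = _glrlm_core(q, n_levels, n_length, dirs[d][0], dirs[d][1])
        acc += _lrlge_from_p(p)
    return acc / 4.0


@njit
def _lrlge_patch(patch, n_levels):
    q = _quantize_core(patch, n_levels)
    return _lrlge_from_q(q, n_levels)


@njit
def _glcm_corr_one(q, n_levels, di, dj):
    """Haralick correlation of the symmetric GLCM at offset (di, dj)."""
    h, w = q.shape
    C = np.zeros((n_levels, n_levels), np.float64)
    for i in range(h):
        for j in range(w):
            ci = i + di
            cj = j + dj
            if 0 <= ci < h and 0 <= cj < w:
                C[q[i, j] - 1, q[ci, cj] - 1] += 1.0
                C[q[ci, cj] - 1, q[i, j] - 1] += 1.0
    tot = C.sum()
    if tot == 0.0:
        return 0.0
    C /= tot
    mu = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            mu += (i + 1.0) * C[i, j]
    var = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            var += (i + 1.0 - mu) * (i + 1.0 - mu) * C[i, j]
    if var < 1e-12:
        return 0.0
    cov = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            cov += (i + 1.0 - mu) * (j + 1.0 - mu) * C[i, j]
    return cov / var


@njit
def _glcm_corr_from_q(q, n_levels):
    acc = 0.0
    dirs = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    for d in range(4):
        acc += _glcm_corr_one(q, n_levels, dirs[d][0], dirs[d][1])
    return acc / 4.0


@njit
def _glcm_corr_patch(patch, n_levels):
    q = _quantize_core(patch, n_levels)
    return _glcm_corr_from_q(q, n_levels)


@njit
def _feature_map_core(image, window, n_gray, n_gradient, code):
    h, w = image.shape
    half = window // 2
    padded = _replicate_pad(image, half)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            patch = padded[i : i + window, j : j + window].copy()
            if code == 0:
                out[i, j] = _idm_patch(patch, n_gray, n_gradient)
            elif code == 1:
                out[i, j] = _lrlge_patch(patch, n_gray)
            else:
                out[i, j] = _glcm_corr_patch(patch, n_gray)
    return out


@njit
def _feature_map_core_global(image, window, n_gray, n_gradient, code):
    """Image-level quantization (f_M, g_M over the whole image), then
    sliding-window statistics over the pre-quantized levels."""
    h, w = image.shape
    half = window // 2
    F = _quantize_core(image, n_gray)
    G = _quantize_core(_sobel_core(image), n_gradient)
    Fp = _replicate_pad(F, half)
    Gp = _replicate_pad(G, half)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            qf = Fp[i : i + window, j : j + window].copy()
            if code == 0:
                qg = Gp[i : i + window, j : j + window].copy()
                H = _ggcm_core(qf, qg, n_gray, n_gradient)
                out[i, j] = _idm_from_H(H)
            elif code == 1:
                out[i, j] = _lrlge_from_q(qf, n_gray)
            else:
                out[i, j] = _glcm_corr_from_q(qf, n_gray)
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class QuantizedImage:
    levels: np.ndarray  # int levels in [1, n_levels]
    n_levels: int
    source_max: float  # f_M of the patch


@dataclass
class GradientImage:
    magnitude: np.ndarray  # Sobel gradient magnitude g(K, L)
    levels: np.ndarray  # quantized gradient levels in [1, n_levels]
    n_levels: int
    source_max: float  # g_M of the patch


@dataclass
class GrayGradientCooccurrence:
    counts: np.ndarray  # H, int counts summing to the patch pixel count
    probabilities: np.ndarray  # P = H / ΣH


def _as_patch(patch) -> np.ndarray:
    patch = np.ascontiguousarray(patch, dtype=float)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a nonempty 2D array")
    if np.any(patch < 0) or not np.all(np.isfinite(patch)):
        raise ValueError("patch must be finite and nonnegative")
    return patch


def quantize_gray(patch, n_levels: int = DEFAULT_N_GRAY) -> QuantizedImage:
    """Normalize a patch to integer gray levels in [1, n_levels]."""
    patch = _as_patch(patch)
    levels = _quantize_core(patch, n_levels)
    return QuantizedImage(levels=levels, n_levels=n_levels, source_max=float(patch.max()))


def sobel_gradient(patch, n_levels: int = DEFAULT_N_GRADIENT) -> GradientImage:
    """Sobel gradient magnitude of a patch, plus its quantized levels."""
    patch = _as_patch(patch)
    g = _sobel_core(patch)
    levels = _quantize_core(g, n_levels)
    return GradientImage(magnitude=g, levels=levels, n_levels=n_levels, source_max=float(g.max()))


def ggcm(
    patch,
    n_gray: int = DEFAULT_N_GRAY,
    n_gradient: int = DEFAULT_N_GRADIENT,
) -> GrayGradientCooccurrence:
    """Gray level-gradient cooccurrence matrix of a patch."""
    patch = _as_patch(patch)
    F = _quantize_core(patch, n_gray)
    G = _quantize_core(_sobel_core(patch), n_gradient)
    H = _ggcm_core(F, G, n_gray, n_gradient)
    return GrayGradientCooccurrence(counts=H, probabilities=H / H.sum())


def idm(P: np.ndarray) -> float:
    """Inverse difference moment Σ_ij P(i,j)/(1+(i−j)²) of a normalized GGCM."""
    P = np.ascontiguousarray(P, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must be normalized (sum to 1)")
    i = np.arange(P.shape[0])[:, None]
    j = np.arange(P.shape[1])[None, :]
    return float((P / (1.0 + (i - j) ** 2)).sum())


def glrlm(levels: np.ndarray, n_levels: int, direction: int) -> np.ndarray:
    """Run-length matrix p(i, j) of a quantized patch along one direction.

    ``levels`` holds integers in [1, n_levels]; ``direction`` is one of
    0, 45, 90, 135 (degrees).  Runs are maximal: a streak of length j
    contributes a single count in column j.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    levels = np.ascontiguousarray(levels, dtype=np.int64)
    if levels.ndim != 2 or levels.size == 0:
        raise ValueError("levels must be a nonempty 2D array")
    if levels.min() < 1 or levels.max() > n_levels:
        raise ValueError(f"levels must lie in [1, {n_levels}]")
    di, dj = DIRECTIONS[direction]
    n_length = max(levels.shape)
    return _glrlm_core(levels, n_levels, n_length, di, dj)


def lrlge(p: np.ndarray) -> float:
    """Long-run low gray-level emphasis (1/n_r) Σ p(i,j)·j²/i² of one GLRLM."""
    p = np.ascontiguousarray(p, dtype=np.int64)
    if p.sum() == 0:
        raise ValueError("run-length matrix is empty (no runs)")
    return float(_lrlge_from_p(p))


def lrlge_mean(patch, n_levels: int = DEFAULT_N_GRAY) -> float:
    """Direction-averaged LRLGE of a raw patch (quantized window-locally)."""
    patch = _as_patch(patch)
    return float(_lrlge_patch(patch, n_levels))


def glcm_correlation(
    patch, n_levels: int = DEFAULT_N_GRAY, direction: int | None = None
) -> float:
    """Haralick correlation of the symmetric GLCM.

    Averaged over the four canonical unit offsets by default, or evaluated at
    a single ``direction`` (0/45/90/135 degrees); windows with zero
    gray-level variance return 0.
    """
    patch = _as_patch(patch)
    if direction is None:
        return float(_glcm_corr_patch(patch, n_levels))
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    di, dj = DIRECTIONS[direction]
    q = _quantize_core(patch, n_levels)
    return float(_glcm_corr_one(q, n_levels, di, dj))


def feature_image(
    image,
    descriptor: str,
    window_size: int | None = None,
    n_gray: int = DEFAULT_N_GRAY,
    n_gradient: int = DEFAULT_N_GRADIENT,
    edge_policy: str = "replicate",
    normalization: str = "global",
) -> np.ndarray:
    """Sliding-window descriptor map of an image.

    ``descriptor`` is ``'idm'``, ``'lrlge'`` or ``'glcm_correlation'``; the
    default window is 5×5 for the cooccurrence descriptors and 3×3 for the
    run-length descriptor.  Borders are replicate-padded.

    ``normalization`` selects where the quantization maxima (f_M, g_M) come
    from: ``'global'`` (default) quantizes the whole image once and computes
    window statistics over the shared levels, so the maps discriminate
    absolute regional structure; ``'window'`` re-normalizes inside every
    window, yielding pure local-contrast descriptors (the per-patch functions
    in this module always behave window-locally).
    """
    if descriptor not in _DESCRIPTOR_CODES:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    if edge_policy != "replicate":
        raise ValueError("only 'replicate' edge handling is supported")
    if normalization not in ("window", "global"):
        raise ValueError("normalization must be 'window' or 'global'")
    image = _as_patch(image)
    if window_size is None:
        window_size = _DEFAULT_WINDOWS[descriptor]
    if window_size % 2 != 1 or window_size < 1:
        raise ValueError("window_size must be odd and positive")
    if window_size > min(image.shape):
        raise ValueError("window_size exceeds image size")
    core = _feature_map_core if normalization == "window" else _feature_map_core_global
    return core(image, window_size, n_gray, n_gradient, _DESCRIPTOR_CODES[descriptor])
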