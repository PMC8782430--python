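"""MLEM and kernelized EM (KEM) reconstruction for Poisson sinogram data.

Both algorithms maximize the Poisson log-likelihood
``L(x) = Σ_i y_i log(ȳ_i) − ȳ_i`` with ``ȳ = P x + r`` (P the attenuated
system operator, r the known expected background).  MLEM is the classical
multiplicative update

    x ← x / (Pᵀ 1_M) · Pᵀ( y / (P x + r) )

KEM parameterizes the image as ``x = K α`` through the feature-similarity
kernel K and iterates the same EM update on the coefficients:

    α ← α / (Kᵀ Pᵀ 1_M) · Kᵀ Pᵀ( y / (P K α + r) )

with the final image estimate ``x̂ = K α̂``.  With K = I the two algorithms
follow the identical code path and produce identical iterates.

Numerical conventions: α (and x) start at 1 inside the field-of-view mask;
pixels with zero sensitivity are frozen at 0; EM-ratio denominators are
floored at 1e-12 of their positive mean; the background r enters the
denominator only.  Nonnegativity is preserved by construction and the
log-likelihood is non-decreasing iteration to iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import KernelMatrix
from .phantom import DynamicSeries

__all__ = ["ReconSettings", "ReconResult", "mlem", "kem", "reconstruct_dynamic"]

_METHODS = ("mlem", "kem", "kem_glcm", "kem_dual")


@dataclass
class ReconSettings:
    iterations: int = 100
    init_value: float = 1.0
    epsilon: float = 1e-12  # denominator floor, relative to the denominator mean

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ReconResult:
    image: np.ndarray  # x̂ (for KEM: K α̂)
    coefficients: np.ndarray  # α̂ (equals image for MLEM)
    loglik: np.ndarray  # Poisson log-likelihood after each iteration


def _floor(arr: np.ndarray, epsilon: float) -> np.ndarray:
    pos = arr[arr > 0]
    tiny = epsilon * (pos.mean() if pos.size else 1.0)
    return np.maximum(arr, tiny)


def _poisson_loglik(y: np.ndarray, ybar: np.ndarray) -> float:
    ybar = np.maximum(ybar, 1e-300)
    mask = y > 0
    return float((y[mask] * np.log(ybar[mask])).sum() - ybar.sum())


def _em_iterations(
    y: np.ndarray,
    model,
    K: KernelMatrix | None,
    r: np.ndarray | None,
    settings: ReconSettings,
) -> ReconResult:
    y = np.asarray(y, dtype=float)
    if y.shape != tuple(model.sino_shape):
        raise ValueError(f"sinogram shape {y.shape} != model {tuple(model.sino_shape)}")
    if np.any(y < 0):
        raise ValueError("measured sinogram must be nonnegative")
    if r is None:
        r = np.zeros_like(y)
    else:
        r = np.asarray(r, dtype=float)
        if r.shape != y.shape:
            raise ValueError("background shape mismatch")
        if np.any(r < 0):
            raise ValueError("background must be nonnegative")

    mask = getattr(model, "mask", None)
    if mask is None:
        mask = np.ones(model.image_shape, dtype=bool)

    sens_img = model.sensitivity()
    if K is not None:
        if K.image_shape != tuple(model.image_shape):
            raise ValueError("kernel image shape does not match the system model")
        sens = K.apply_transpose(sens_img)
    else:
        sens = sens_img
    alive = (sens > 0) & mask

    alpha = np.where(alive, settings.init_value, 0.0)
    sens_safe = np.where(alive, sens, 1.0)
    trace = np.empty(settings.iterations)
    for it in range(settings.iterations):
        x = K.apply(alpha) if K is not None else alpha
        ybar = model.forward_project(x) + r
        ratio = y / _floor(ybar, settings.epsilon)
        back = model.back_project(ratio)
        if K is not None:
            back = K.apply_transpose(back)
        alpha = np.where(alive, alpha * back / sens_safe, 0.0)
        x = K.apply(alpha) if K is not None else alpha
        trace[it] = _poisson_loglik(y, model.forward_project(x) + r)
    return ReconResult(image=x, coefficients=alpha, loglik=trace)


def mlem(
    y: np.ndarray,
    model,
    r: np.ndarray | None = None,
    settings: ReconSettings | None = None,
) -> ReconResult:
    """Maximum-likelihood EM reconstruction of one sinogram."""
    return _em_iterations(y, model, None, r, settings or ReconSettings())


def kem(
    y: np.ndarray,
    model,
    K: KernelMatrix,
    r: np.ndarray | None = None,
    settings: ReconSettings | None = None,
) -> ReconResult:
    """Kernelized EM reconstruction; returns α̂ and x̂ = K α̂."""
    if K is None:
        raise ValueError("kem requires a kernel matrix (use mlem otherwise)")
    return _em_iterations(y, model, K, r, settings or ReconSettings())


def reconstruct_dynamic(
    series: DynamicSeries,
    model,
    method: str = "mlem",
    K: KernelMatrix | None = None,
    r: np.ndarray | None = None,
    settings: ReconSettings | None = None,
) -> DynamicSeries:
    """Reconstruct every frame of a dynamic sinogram series independently.

    ``method`` ∈ {mlem, kem, kem_glcm, kem_dual}; the kernelized methods share
    one kernel K across all frames (the kernel encodes which features built
    it).  ``r`` may be a single background sinogram or a per-frame stack.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if series.kind != "sinogram":
        raise ValueError("reconstruct_dynamic expects sinogram-space data")
    kernelized = method != "mlem"
    if kernelized and K is None:
        raise ValueError(f"method {method!r} requires a kernel matrix")
    settings = settings or ReconSettings()
    if r is not None:
        r = np.asarray(r, dtype=float)
        if r.ndim == 2:
            r = np.broadcast_to(r, series.frames.shape)
    images = []
    for i, y in enumerate(series.frames):
        ri = None if r is None else r[i]
        res = _em_iterations(y, model, K if kernelized else None, ri, settings)
        images.append(res.image)
    return DynamicSeries(series.schedule, np.stack(images), "image")
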