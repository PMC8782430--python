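"""Per-pixel feature fields and the sparse Gaussian kernel matrix K.

The kernelized-EM image model is ``x = K α``: each pixel's activity is a
kernel-weighted combination of coefficients at pixels with *similar prior
features*.  Features come from three composite-frame prior reconstructions:
for the dual-texture method each pixel carries a 9-vector (three prior
intensities, three IDM values, three LRLGE values), z-scored per channel over
the field-of-view mask.  Similarity is the Gaussian kernel
``κ(f_j, f_l) = exp(−‖f_j − f_l‖² / 2σ²)`` restricted to each pixel's k
nearest neighbors (Euclidean distance in feature space) within a spatial
search window; the self term κ=1 is always kept.  Rows are normalized to unit
sum by default so that K applied to a constant image returns that constant,
which keeps the reconstruction quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import texture

__all__ = [
    "FeatureField",
    "KernelMatrix",
    "build_feature_field",
    "feature_field_from_priors",
    "knn_neighbors",
    "build_kernel",
]

_SD_FLOOR = 1e-12


@dataclass
class FeatureField:
    """Z-scored per-pixel feature vectors over an image grid.

    ``channels`` has shape (C, H, W); ``mask`` marks the field of view.
    ``means``/``sds`` are the pre-normalization per-channel statistics over
    the mask (channels with SD below floor are set identically to zero).
    """

    channels: np.ndarray
    mask: np.ndarray
    channel_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


@dataclass
class KernelMatrix:
    """Sparse kernel K with its construction metadata."""

    K: sp.csr_matrix
    image_shape: tuple[int, int]
    sigma: float
    k: int
    search_window: int
    row_normalized: bool

    @classmethod
    def identity(cls, image_shape: tuple[int, int]) -> "KernelMatrix":
        n = int(np.prod(image_shape))
        return cls(
            K=sp.identity(n, format="csr"),
            image_shape=tuple(image_shape),
            sigma=0.0,
            k=0,
            search_window=1,
            row_normalized=True,
        )

    def apply(self, image: np.ndarray) -> np.ndarray:
        return (self.K @ np.asarray(image, dtype=float).ravel()).reshape(self.image_shape)

    def apply_transpose(self, image: np.ndarray) -> np.ndarray:
        return (self.K.T @ np.asarray(image, dtype=float).ravel()).reshape(self.image_shape)


def build_feature_field(
    channels: list[np.ndarray] | np.ndarray,
    mask: np.ndarray | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> FeatureField:
    """Stack raw feature channels and z-score each over the mask.

    Channels whose standard deviation over the mask is below floor (constant
    channels) are set to zero everywhere rather than divided by ~0.
    """
    channels = np.stack([np.asarray(c, dtype=float) for c in channels])
    if channels.ndim != 3:
        raise ValueError("channels must stack to (C, H, W)")
    if not np.all(np.isfinite(channels)):
        raise ValueError("feature channels must be finite")
    if mask is None:
        mask = np.ones(channels.shape[1:], dtype=bool)
    if mask.shape != channels.shape[1:]:
        raise ValueError("mask shape does not match channel shape")
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(channels.shape[0]))

    means = np.array([c[mask].mean() for c in channels])
    sds = np.array([c[mask].std(ddof=0) for c in channels])
    out = np.zeros_like(channels)
    for i, c in enumerate(channels):
        if sds[i] > _SD_FLOOR:
            out[i] = (c - means[i]) / sds[i]
    out[:, ~mask] = 0.0
    return FeatureField(
        channels=out, mask=mask, channel_names=tuple(channel_names), means=means, sds=sds
    )


def feature_field_from_priors(
    priors: list[np.ndarray],
    mask: np.ndarray | None = None,
    descriptors: tuple[str, ...] = ("intensity", "idm", "lrlge"),
    n_gray: int = texture.DEFAULT_N_GRAY,
    normalization: str = "global",
) -> FeatureField:
    """Feature field from composite-frame priors and their texture maps.

    Channel order: all prior intensities first, then each texture descriptor
    across the priors (e.g. for three priors and the dual-texture setting:
    intensity×3, IDM×3, LRLGE×3 → 9 channels).
    """
    shapes = {p.shape for p in priors}
    if len(shapes) != 1:
        raise ValueError("all prior images must share one shape")
    channels: list[np.ndarray] = []
    names: list[str] = []
    for desc in descriptors:
        for i, p in enumerate(priors):
            if desc == "intensity":
                channels.append(np.asarray(p, dtype=float))
            else:
                channels.append(
                    texture.feature_image(p, desc, n_gray=n_gray, normalization=normalization)
                )
            names.append(f"{desc}_{i}")
    return build_feature_field(channels, mask=mask, channel_names=tuple(names))


def knn_neighbors(
    field: FeatureField,
    k: int = 50,
    search_window: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest feature-space neighbors within a spatial search window.

    Returns ``(neighbors, distances)`` of shape (N, k) over flat pixel
    indices; entries are −1 / inf where a pixel (near the mask boundary) has
    fewer than k in-mask candidates.  The center pixel is excluded from its
    own candidate list.  Ties in distance are broken by ascending flat pixel
    index (candidates are enumerated in row-major window order and sorted
    stably).
    """
    if search_window % 2 != 1 or search_window < 3:
        raise ValueError("search_window must be odd and >= 3")
    n_candidates = search_window**2 - 1
    if k > n_candidates:
        raise ValueError(
            f"k={k} exceeds the {n_candidates} candidates in a "
            f"{search_window}×{search_window} window"
        )
    C, H, W = field.channels.shape
    half = search_window // 2
    feats = np.where(field.mask[None], field.channels, np.inf)
    padded = np.full((C, H + 2 * half, W + 2 * half), np.inf)
    padded[:, half : half + H, half : half + W] = feats

    offsets = [
        (dy, dx)
        for dy in range(-half, half + 1)
        for dx in range(-half, half + 1)
        if (dy, dx) != (0, 0)
    ]
    n_off = len(offsets)
    d2 = np.empty((n_off, H * W))
    nbr = np.empty((n_off, H * W), dtype=np.int64)
    yy, xx = np.mgrid[0:H, 0:W]
    center = field.channels.reshape(C, -1)
    for o, (dy, dx) in enumerate(offsets):
        shifted = padded[:, half + dy : half + dy + H, half + dx : half + dx + W]
        diff = shifted.reshape(C, -1) - center
        with np.errstate(invalid="ignore"):
            d2[o] = np.einsum("ij,ij->j", diff, diff)
        ny = yy + dy
        nx = xx + dx
        lin = (ny * W + nx).ravel()
        valid = ((ny >= 0) & (ny < H) & (nx >= 0) & (nx < W)).ravel()
        nbr[o] = np.where(valid, lin, -1)
        d2[o, ~valid] = np.inf
    d2[np.isnan(d2)] = np.inf

    # row-major offset enumeration → candidate flat indices ascend for every
    # pixel, so a stable sort on distance implements the index tie-break
    order = np.argsort(d2, axis=0, kind="stable")[:k]
    cols = np.arange(H * W)
    dist = np.sqrt(d2[order, cols])
    neighbors = nbr[order, cols]
    neighbors[~np.isfinite(dist)] = -1
    out_mask = ~field.mask.ravel()
    neighbors[:, out_mask] = -1
    dist[:, out_mask] = np.inf
    return neighbors.T.copy(), dist.T.copy()


def build_kernel(
    field: FeatureField,
    neighbors: np.ndarray,
    distances: np.ndarray,
    sigma: float = 1.0,
    row_normalize: bool = True,
    search_window: int = 0,
) -> KernelMatrix:
    """Assemble sparse K with κ = exp(−d²/2σ²) on neighbor pairs, κ_jj = 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    H, W = field.image_shape
    n = H * W
    rows_list = [np.arange(n)]
    cols_list = [np.arange(n)]
    vals_list = [np.ones(n)]  # self-similarity
    valid = neighbors >= 0
    r, c = np.nonzero(valid)
    rows_list.append(r)
    cols_list.append(neighbors[valid])
    vals_list.append(np.exp(-distances[valid] ** 2 / (2.0 * sigma**2)))
    K = sp.coo_matrix(
        (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(n, n),
    ).tocsr()
    if row_normalize:
        inv = 1.0 / np.asarray(K.sum(axis=1)).ravel()
        K = sp.diags(inv) @ K
    return KernelMatrix(
        K=K.tocsr(),
        image_shape=(H, W),
        sigma=float(sigma),
        k=int(neighbors.shape[1]),
        search_window=int(search_window),
        row_normalized=bool(row_normalize),
    )
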