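"""Tomographic system model: 2D parallel-beam forward/back projection.

The projector is the linear operator ``P`` that maps a 2D activity image to a
sinogram of shape (n_radial, n_angles).  Emission-tomography EM algorithms
require the backprojector to be the *exact adjoint* of the forward projector
(the convergence proof relies on ``<Px, y> = <x, P^T y>``), so both directions
are implemented by one sparse matrix and its transpose rather than by a pair of
independently discretized operators.

Discretization: each pixel center is projected onto the radial axis of every
view (``r = x cos θ + y sin θ``) and its value is split linearly between the
two nearest radial bins, scaled by 1/Δr so sinogram values approximate line
integrals in pixel units.  Angles are uniform over [0°, 180°); angle zero has
rays parallel to the image y-axis, i.e. the θ=0 profile is the column-sum
profile.  Radial bins span the grid diagonal.  Pixels outside the inscribed
reconstruction circle are never projected and are masked to zero.

Attenuation is modelled as bin-wise multiplicative survival factors in (0, 1]
applied after geometric projection, so the stored operator already realizes
attenuated projection and its exact adjoint.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["SystemModel", "MatrixModel", "attenuation_from_mumap"]

_DEFAULT_N_RADIAL = 249
_DEFAULT_N_ANGLES = 210
_REFERENCE_GRID = 217


def _build_projection_matrix(grid_size: int, n_radial: int, n_angles: int) -> sp.csr_matrix:
    """Assemble the sparse geometric projection matrix (no attenuation).

    Row index = radial_bin * n_angles + angle; column index = flat pixel index.
    """
    n = grid_size
    half = (n - 1) / 2.0
    ds = n * np.sqrt(2.0) / n_radial
    coords = np.arange(n) - half
    xx, yy = np.meshgrid(coords, coords)  # xx varies along columns, yy along rows
    inside = (xx**2 + yy**2) <= (n / 2.0) ** 2
    pix = np.flatnonzero(inside.ravel())
    x = xx.ravel()[pix]
    y = yy.ravel()[pix]

    r_center = (n_radial - 1) / 2.0
    theta = np.pi * np.arange(n_angles) / n_angles
    # (n_pix, n_angles) continuous radial-bin coordinate of every pixel center
    cont = (np.outer(x, np.cos(theta)) + np.outer(y, np.sin(theta))) / ds + r_center
    b0 = np.floor(cont).astype(np.int64)
    frac = cont - b0
    a_idx = np.broadcast_to(np.arange(n_angles, dtype=np.int64), cont.shape)
    p_idx = np.broadcast_to(pix[:, None], cont.shape)
    rows_all, cols_all, vals_all = [], [], []
    for b, w in ((b0, (1.0 - frac) / ds), (b0 + 1, frac / ds)):
        ok = (b >= 0) & (b < n_radial) & (w > 0)
        rows_all.append((b[ok] * n_angles + a_idx[ok]).astype(np.int32))
        cols_all.append(p_idx[ok].astype(np.int32))
        vals_all.append(w[ok])
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    P = sp.coo_matrix((vals, (rows, cols)), shape=(n_radial * n_angles, n * n))
    return P.tocsr()


class SystemModel:
    """Parallel-beam system model ``y = A ⊙ (P x)`` with exact adjoint.

    Parameters
    ----------
    grid_size : int
        Image side length in pixels.
    n_radial, n_angles : int
        Sinogram dimensions; defaults are 249 radial bins and 210 uniformly
        spaced angles.
    attenuation : ndarray, optional
        Per-bin survival factors in (0, 1], shape (n_radial, n_angles).
    """

    def __init__(
        self,
        grid_size: int,
        n_radial: int = _DEFAULT_N_RADIAL,
        n_angles: int = _DEFAULT_N_ANGLES,
        attenuation: np.ndarray | None = None,
    ):
        if grid_size < 8:
            raise ValueError("grid_size must be at least 8")
        self.grid_size = int(grid_size)
        self.n_radial = int(n_radial)
        self.n_angles = int(n_angles)
        self.ds = grid_size * np.sqrt(2.0) / n_radial
        self._P = _build_projection_matrix(self.grid_size, self.n_radial, self.n_angles)
        self._PT = self._P.T.tocsr()
        n = self.grid_size
        coords = np.arange(n) - (n - 1) / 2.0
        xx, yy = np.meshgrid(coords, coords)
        self.mask = (xx**2 + yy**2) <= (n / 2.0) ** 2
        self.attenuation = None
        if attenuation is not None:
            self.set_attenuation(attenuation)

    @classmethod
    def for_grid(cls, grid_size: int, attenuation: np.ndarray | None = None) -> "SystemModel":
        """Model with sinogram dimensions scaled proportionally from the
        reference 217-pixel grid (which uses 249 × 210)."""
        scale = grid_size / _REFERENCE_GRID
        n_radial = max(16, int(round(_DEFAULT_N_RADIAL * scale)))
        n_angles = max(16, int(round(_DEFAULT_N_ANGLES * scale)))
        return cls(grid_size, n_radial=n_radial, n_angles=n_angles, attenuation=attenuation)

    # -- shapes -----------------------------------------------------------
    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.grid_size, self.grid_size)

    @property
    def sino_shape(self) -> tuple[int, int]:
        return (self.n_radial, self.n_angles)

    @property
    def n_bins(self) -> int:
        """M, the number of sinogram bins."""
        return self.n_radial * self.n_angles

    def set_attenuation(self, factors: np.ndarray) -> None:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != self.sino_shape:
            raise ValueError(
                f"attenuation shape {factors.shape} != sinogram shape {self.sino_shape}"
            )
        if np.any(factors <= 0) or np.any(factors > 1):
            raise ValueError("attenuation factors must lie in (0, 1]")
        self.attenuation = factors

    # -- operators --------------------------------------------------------
    def _check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.image_shape:
            raise ValueError(f"image shape {image.shape} != {self.image_shape}")
        return image

    def _check_sino(self, sino: np.ndarray) -> np.ndarray:
        sino = np.asarray(sino, dtype=float)
        if sino.shape != self.sino_shape:
            raise ValueError(f"sinogram shape {sino.shape} != {self.sino_shape}")
        return sino

    def geometric_forward(self, image: np.ndarray) -> np.ndarray:
        """Forward projection without attenuation (pure line integrals)."""
        image = self._check_image(image)
        return (self._P @ image.ravel()).reshape(self.sino_shape)

    def forward_project(self, image: np.ndarray) -> np.ndarray:
        """y = A ⊙ (P x); attenuation applied bin-wise if set."""
        sino = self.geometric_forward(image)
        if self.attenuation is not None:
            sino = sino * self.attenuation
        return sino

    def back_project(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward_project`."""
        sino = self._check_sino(sino)
        if self.attenuation is not None:
            sino = sino * self.attenuation
        return (self._PT @ sino.ravel()).reshape(self.image_shape)

    def sensitivity(self) -> np.ndarray:
        """Backprojection of the all-ones sinogram, Pᵀ(A ⊙ 1_M)."""
        return self.back_project(np.ones(self.sino_shape))


class MatrixModel:
    """Wrap an explicit dense/sparse matrix as a system model.

    Useful for toy systems with hand-checkable solutions; exposes the same
    forward/back/sensitivity surface as :class:`SystemModel`.
    """

    def __init__(self, A, image_shape: tuple[int, ...], sino_shape: tuple[int, ...]):
        self.A = A
        self.image_shape = tuple(image_shape)
        self.sino_shape = tuple(sino_shape)
        self.mask = np.ones(self.image_shape, dtype=bool)
        self.attenuation = None

    def forward_project(self, image):
        image = np.asarray(image, dtype=float)
        if image.shape != self.image_shape:
            raise ValueError("image shape mismatch")
        return np.asarray(self.A @ image.ravel()).reshape(self.sino_shape)

    def back_project(self, sino):
        sino = np.asarray(sino, dtype=float)
        if sino.shape != self.sino_shape:
            raise ValueError("sinogram shape mismatch")
        return np.asarray(self.A.T @ sino.ravel()).reshape(self.image_shape)

    def sensitivity(self):
        return self.back_project(np.ones(self.sino_shape))


def attenuation_from_mumap(mu_image: np.ndarray, model: SystemModel) -> np.ndarray:
    """Beer–Lambert survival factors exp(−∫μ dl) per sinogram bin.

    ``mu_image`` is a linear attenuation map in inverse pixel units; line
    integrals use the model's geometric projector so the factors are exactly
    consistent with the emission operator.
    """
    mu_image = np.asarray(mu_image, dtype=float)
    if np.any(mu_image < 0):
        raise ValueError("attenuation map must be nonnegative")
    line_integrals = model.geometric_forward(mu_image)
    return np.exp(-line_integrals)
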