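"""Independent pure-Python brute-force reference implementations.

Deliberately written with a different structure from the package code (plain
loops, line extraction + groupby for runs) so that agreement is a meaningful
cross-check and not a tautology.
"""

import itertools
import math

import numpy as np


def brute_quantize(patch, n_levels):
    patch = np.asarray(patch, dtype=float)
    fm = patch.max()
    out = np.ones(patch.shape, dtype=int)
    if fm <= 0:
        return out
    for idx in np.ndindex(patch.shape):
        lev = math.floor(patch[idx] * n_levels / fm) + 1
        out[idx] = min(max(lev, 1), n_levels)
    return out


def _pix(patch, i, j):
    # replicate padding semantics
    i = min(max(i, 0), patch.shape[0] - 1)
    j = min(max(j, 0), patch.shape[1] - 1)
    return patch[i, j]


def brute_sobel(patch):
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    g = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gx = (
                _pix(patch, i + 1, j - 1) + 2 * _pix(patch, i + 1, j) + _pix(patch, i + 1, j + 1)
                - _pix(patch, i - 1, j - 1) - 2 * _pix(patch, i - 1, j) - _pix(patch, i - 1, j + 1)
            )
            gy = (
                _pix(patch, i - 1, j + 1) + 2 * _pix(patch, i, j + 1) + _pix(patch, i + 1, j + 1)
                - _pix(patch, i - 1, j - 1) - 2 * _pix(patch, i, j - 1) - _pix(patch, i + 1, j - 1)
            )
            g[i, j] = math.hypot(gx, gy)
    return g


def brute_ggcm(patch, n_gray, n_gradient):
    F = brute_quantize(patch, n_gray)
    G = brute_quantize(brute_sobel(patch), n_gradient)
    H = np.zeros((n_gray, n_gradient), dtype=int)
    for i in range(1, n_gray + 1):
        for j in range(1, n_gradient + 1):
            H[i - 1, j - 1] = int(np.sum((F == i) & (G == j)))
    return H


def brute_idm(P):
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            total += P[i, j] / (1 + (i - j) ** 2)
    return total


def _lines(levels, direction):
    """Extract all 1D lines of a 2D array along a direction."""
    a = np.asarray(levels)
    if direction == 0:
        return [row.tolist() for row in a]
    if direction == 90:
        return [col.tolist() for col in a.T]
    if direction == 45:
        # bottom-left to top-right diagonals
        flipped = np.flipud(a)
        return [np.diagonal(flipped, off).tolist() for off in range(-a.shape[0] + 1, a.shape[1])]
    if direction == 135:
        return [np.diagonal(a, off).tolist() for off in range(-a.shape[0] + 1, a.shape[1])]
    raise ValueError(direction)


def brute_glrlm(levels, n_levels, direction):
    levels = np.asarray(levels)
    n_length = max(levels.shape)
    p = np.zeros((n_levels, n_length), dtype=int)
    for line in _lines(levels, direction):
        for value, group in itertools.groupby(line):
            p[value - 1, len(list(group)) - 1] += 1
    return p


def brute_lrlge(p):
    nr = p.sum()
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            total += p[i, j] * (j + 1) ** 2 / (i + 1) ** 2
    return total / nr


def brute_lrlge_mean(patch, n_levels):
    q = brute_quantize(patch, n_levels)
    vals = [brute_lrlge(brute_glrlm(q, n_levels, d)) for d in (0, 45, 90, 135)]
    return sum(vals) / 4


def brute_glcm_correlation(patch, n_levels, direction):
    q = brute_quantize(patch, n_levels)
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    di, dj = offsets[direction]
    h, w = q.shape
    C = np.zeros((n_levels, n_levels))
    for i in range(h):
        for j in range(w):
            ci, cj = i + di, j + dj
            if 0 <= ci < h and 0 <= cj < w:
                C[q[i, j] - 1, q[ci, cj] - 1] += 1
                C[q[ci, cj] - 1, q[i, j] - 1] += 1
    if C.sum() == 0:
        return 0.0
    P = C / C.sum()
    levels = np.arange(1, n_levels + 1)
    mu = float((levels[:, None] * P).sum())
    var = float((((levels - mu) ** 2)[:, None] * P).sum())
    if var < 1e-12:
        return 0.0
    cov = float(((levels[:, None] - mu) * (levels[None, :] - mu) * P).sum())
    return cov / var
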