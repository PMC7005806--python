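"""Dimension-agnostic displacement-field primitives.

All functions operate on raw arrays: an image is a ``d``-dimensional array,
a field is an array of shape ``(d, *spatial)`` whose component ``i`` holds
the displacement along axis ``i`` in voxel units.  Fields are pull-back
maps: warping an image ``I`` by field ``u`` produces
``out(q) = I(q + u(q))``.

These primitives back both the registration optimizer (2D and 3D) and the
public :mod:`brainsmapi.feature_registration` operations.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "nearest_sample",
    "trilinear_sample",
    "identity_grid",
    "warp_image",
    "warp_affine_image",
    "sample_field",
    "compose",
    "invert",
    "exp_field",
    "smooth_field",
    "jacobian_determinant",
]


def nearest_sample(arr: np.ndarray, coords: np.ndarray, fill=0) -> np.ndarray:
    """Nearest-neighbour gather at continuous ``coords`` of shape ``(d, N)``.

    The rounding rule is ``floor(c + 0.5)`` (half-up), chosen because it
    commutes exactly with integer coordinate offsets — the property that
    makes block-wise warping bit-identical to whole-volume warping.
    Out-of-bounds samples return ``fill``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    idx = np.floor(coords + 0.5).astype(np.int64)
    valid = np.ones(idx.shape[1:], dtype=bool)
    for d, size in enumerate(arr.shape):
        valid &= (idx[d] >= 0) & (idx[d] < size)
    safe = tuple(np.clip(idx[d], 0, arr.shape[d] - 1) for d in range(arr.ndim))
    out = arr[safe].copy()
    out[~valid] = fill
    return out


def trilinear_sample(arr: np.ndarray, coords: np.ndarray, fill: float = 0.0,
                     mode: str = "constant") -> np.ndarray:
    """Hand-rolled n-linear (bilinear/trilinear) interpolation at ``coords``.

    ``coords`` has shape ``(d, N)``.  ``mode='constant'`` treats samples
    outside the array as ``fill``; ``mode='clamp'`` clamps coordinates to
    the boundary cells (constant extension of edge values).  At exact grid
    nodes the weights collapse so the stored value is returned bit-exactly.
    """
    coords = np.asarray(coords, dtype=np.float64)
    d = arr.ndim
    if mode == "clamp":
        coords = np.stack([np.clip(coords[a], 0.0, arr.shape[a] - 1.0) for a in range(d)])
    i0 = np.floor(coords).astype(np.int64)
    frac = coords - i0
    out = np.zeros(coords.shape[1:], dtype=np.float64)
    arrf = arr.astype(np.float64, copy=False)
    for corner in range(1 << d):
        offs = [(corner >> a) & 1 for a in range(d)]
        idx = [i0[a] + offs[a] for a in range(d)]
        w = np.ones_like(out)
        for a in range(d):
            w = w * (frac[a] if offs[a] else (1.0 - frac[a]))
        valid = np.ones(out.shape, dtype=bool)
        for a in range(d):
            valid &= (idx[a] >= 0) & (idx[a] < arr.shape[a])
        safe = tuple(np.clip(idx[a], 0, arr.shape[a] - 1) for a in range(d))
        vals = np.where(valid, arrf[safe], fill)
        out += w * vals
    return out


def identity_grid(shape) -> np.ndarray:
    """Voxel-index grid of shape ``(d, *shape)`` (float64)."""
    axes = np.indices(shape, dtype=np.float64)
    return axes


def warp_image(img: np.ndarray, field: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Pull-back warp: ``out(q) = img(q + field(q))``; outside -> ``cval``."""
    coords = identity_grid(img.shape) + field
    return ndimage.map_coordinates(img, coords, order=order, mode="constant", cval=cval)


def warp_affine_image(img: np.ndarray, matrix: np.ndarray, order: int = 1,
                      cval: float = 0.0, out_shape=None,
                      mode: str = "constant") -> np.ndarray:
    """Pull-back warp by a homogeneous row-vector affine: ``out(q) = img([q,1] @ M)``.

    ``mode="nearest"`` clamps out-of-bounds samples to the border instead of
    filling with ``cval``; optimization metrics use it because the constant
    fill makes the cost discontinuous whenever a border sample crosses the
    image edge (e.g. exactly at the identity transform).
    """
    d = img.ndim
    out_shape = tuple(out_shape) if out_shape is not None else img.shape
    grid = identity_grid(out_shape).reshape(d, -1).T  # (N, d)
    src = grid @ matrix[:d, :d] + matrix[d, :d]
    coords = src.T.reshape((d,) + out_shape)
    return ndimage.map_coordinates(img, coords, order=order, mode=mode, cval=cval)


def sample_field(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample each component of ``field`` at continuous voxel ``coords``.

    ``coords`` has shape ``(d, *any)``; edge behaviour is clamp-to-boundary
    (constant extension of boundary vectors).
    """
    return np.stack(
        [ndimage.map_coordinates(c, coords, order=1, mode="nearest") for c in field]
    )


def compose(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Displacement composition ``(f o g)(x) = g(x) + f(x + g(x))``.

    Warping by the result equals warping by ``g`` after warping by ``f``:
    ``I((id+f) o (id+g)) = I o (id + compose(f, g))``.
    """
    if f.shape != g.shape:
        raise ValueError(f"field shapes differ: {f.shape} vs {g.shape}")
    coords = identity_grid(f.shape[1:]) + g
    return g + sample_field(f, coords)


def invert(f: np.ndarray, iters: int = 50, tol: float = 1e-2):
    """Fixed-point inverse: find g with ``compose(f, g) ~ 0``.

    Iterates ``g <- -f(x + g(x))``.  Returns ``(g, residual)`` where the
    residual is the max norm of the composition after the last iteration.
    """
    grid = identity_grid(f.shape[1:])
    g = -f
    residual = np.inf
    for _ in range(int(iters)):
        g = -sample_field(f, grid + g)
        residual = float(np.sqrt(((g + sample_field(f, grid + g)) ** 2).sum(axis=0)).max())
        if residual < tol:
            break
    return g, residual


def exp_field(v: np.ndarray, max_half_norm: float = 0.5) -> np.ndarray:
    """Exponential of a stationary velocity field by scaling and squaring.

    Scales ``v`` down until its max vector norm is below ``max_half_norm``,
    then squares (self-composes) the small displacement back up.  The result
    is a diffeomorphic displacement with ``exp(v)`` and ``exp(-v)`` mutual
    inverses up to the squaring tolerance.
    """
    maxnorm = float(np.sqrt((v.astype(np.float64) ** 2).sum(axis=0)).max())
    if maxnorm == 0.0:
        return v.copy()
    n = max(0, int(np.ceil(np.log2(maxnorm / max_half_norm))))
    u = v / (2.0 ** n)
    for _ in range(n):
        u = compose(u, u)
    return u


def smooth_field(f: np.ndarray, sigma: float) -> np.ndarray:
    """Component-wise Gaussian smoothing (no-op for sigma <= 0)."""
    if sigma <= 0:
        return f
    return np.stack([ndimage.gaussian_filter(c, sigma, mode="nearest") for c in f])


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Finite-difference Jacobian determinant of the map ``id + field``."""
    d = field.shape[0]
    J = np.empty(field.shape[1:] + (d, d))
    for i in range(d):
        grads = np.gradient(field[i])
        for j in range(d):
            J[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    return np.linalg.det(J)
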