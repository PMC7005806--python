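"""Transformation obtaining at working resolution (default 10 um).

Registration is driven by encodings of manually delineated regional
features rather than raw gray values: each selected region becomes one
scalar channel (Gaussian-smoothed indicator or signed distance), and both
the affine and the diffeomorphic stage optimize a multi-channel similarity.

The diffeomorphic stage is a symmetric compositional optimizer in the log
domain: a single stationary velocity field ``v`` is updated from forces
computed in both registration directions, and the output displacement pair
is ``phi2 = exp(v)`` (pull-back, warps the moving image onto the fixed one)
and ``phi1 = exp(-v)`` (forward/direct, pushes moving-space points into
fixed space).  Symmetry and invertibility therefore hold by construction,
up to the scaling-and-squaring tolerance.  The optimizer works unchanged in
2D (the cartoon-face experiment) and 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from . import fields
from .types import (
    AffineTransform,
    ConvergenceError,
    DisplacementField,
    LabelVolume,
    ValidationError,
    Volume3D,
)

__all__ = [
    "FeatureImage",
    "RegistrationConfig",
    "RegistrationResult",
    "encode_features",
    "register_affine",
    "register_diffeomorphic",
    "compose_fields",
    "invert_field",
    "apply_transform_lowres",
]


@dataclass
class FeatureImage:
    """One scalar channel per selected region, stacked as ``(C, *spatial)``."""

    channels: np.ndarray
    region_ids: list
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.shape[0] != len(self.region_ids):
            raise ValidationError("channel count must equal len(region_ids)")
        if not np.all(np.isfinite(self.channels)):
            raise ValidationError("feature encodings must be finite")

    @property
    def spatial_shape(self):
        return self.channels.shape[1:]

    @property
    def ndim(self):
        return self.channels.ndim - 1


@dataclass
class RegistrationConfig:
    levels: tuple = (4, 2, 1)            # multiresolution shrink factors, descending
    iters_per_level: tuple = (100, 80, 50)
    update_sigma: float = 2.0            # px, fluid-like smoothing of each update
    field_sigma: float = 0.5             # px, elastic-like smoothing of the velocity
    step: float = 2.0                    # max update vector norm, voxels
    metric: str = "ssd"                  # ssd | mi
    seed: int = 0
    affine_maxiter: int = 80
    patience: int = 8

    def __post_init__(self):
        if list(self.levels) != sorted(self.levels, reverse=True):
            raise ValidationError("levels must be descending shrink factors")
        if self.update_sigma < 0 or self.field_sigma < 0:
            raise ValidationError("sigmas must be >= 0")
        if self.step <= 0:
            raise ValidationError("step must be > 0")
        if self.metric not in ("ssd", "mi"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        if len(self.iters_per_level) != len(self.levels):
            raise ValidationError("iters_per_level must match levels")


@dataclass
class RegistrationResult:
    """Outputs of transformation obtaining: linear matrix + field pair.

    ``phi2`` is expressed in the convention of :func:`apply_transform_lowres`
    (source = ``[q] @ M + phi2(q)``) so that ``apply_transform_lowres(moving,
    M, phi2)`` warps the moving image onto the fixed one.  ``phi1`` is the
    forward field in the affine-prealigned frame: a moving-space point ``p``
    maps to ``q = [p] @ M^-1`` then ``q + phi1(q)`` in fixed space.  When the
    initial affine is the identity, ``phi1`` and ``phi2`` are mutual
    inverses.
    """

    M: AffineTransform
    phi1: DisplacementField
    phi2: DisplacementField
    energy_trace: list = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# feature encoding

def _resolve_regions(lv: LabelVolume, regions) -> list[int]:
    name_to_id = {v: k for k, v in lv.names.items()}
    ids, missing = [], []
    for r in regions:
        if isinstance(r, str):
            if r in name_to_id:
                ids.append(name_to_id[r])
            else:
                missing.append(r)
        else:
            if int(r) in lv.names:
                ids.append(int(r))
            else:
                missing.append(r)
    if missing:
        raise ValidationError(f"regions absent from label volume: {missing}")
    return ids


def encode_features(lv, regions, encoding: str = "onehot",
                    sigma: float = 1.5, cap: float = 10.0) -> FeatureImage:
    """Encode selected regions as registration channels.

    ``lv`` is a :class:`LabelVolume`, or a plain integer label array of any
    dimensionality (the planar model experiment passes 2D label images; region
    ids must then be integers).

    ``onehot``: Gaussian-smoothed indicator per region (sigma in voxels).
    ``distance``: signed Euclidean distance to the region boundary, positive
    inside, clamped to ``+-cap`` voxels.
    """
    if isinstance(lv, LabelVolume):
        ids = _resolve_regions(lv, regions)
        labels = lv.labels
        voxel_size = lv.voxel_size
    else:
        labels = np.asarray(lv)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("label array must be integer-typed")
        ids = [int(r) for r in regions]
        present = set(np.unique(labels).tolist())
        missing = [r for r in ids if r not in present]
        if missing:
            raise ValidationError(f"regions absent from label array: {missing}")
        voxel_size = (1.0,) * labels.ndim
    channels = []
    for r in ids:
        m = labels == r
        if encoding == "onehot":
            c = m.astype(np.float32)
            if sigma > 0:
                c = ndimage.gaussian_filter(c, sigma)
        elif encoding == "distance":
            inside = ndimage.distance_transform_edt(m)
            outside = ndimage.distance_transform_edt(~m)
            c = np.clip(inside - outside, -cap, cap).astype(np.float32)
        else:
            raise ValidationError(f"unknown encoding {encoding!r}")
        channels.append(c)
    return FeatureImage(np.stack(channels), ids, voxel_size)


# ---------------------------------------------------------------------------
# shared helpers

def _downsample_channels(ch: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return ch
    sm = np.stack([ndimage.gaussian_filter(c, factor / 3.0) for c in ch])
    spatial = ch.shape[1:]
    target = tuple(max(4, int(round(s / factor))) for s in spatial)
    zoom = [t / s for t, s in zip(target, spatial)]
    return np.stack([ndimage.zoom(c, zoom, order=1, mode="nearest") for c in sm])


def _upsample_field(v: np.ndarray, target_shape) -> np.ndarray:
    src_shape = v.shape[1:]
    if tuple(src_shape) == tuple(target_shape):
        return v
    zoom = [t / s for t, s in zip(target_shape, src_shape)]
    return np.stack([
        ndimage.zoom(v[d], zoom, order=1, mode="nearest") * zoom[d]
        for d in range(v.shape[0])
    ])


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / max(h.sum(), 1.0)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


# ---------------------------------------------------------------------------
# affine stage

def _level_matrix(matrix: np.ndarray, factor: float) -> np.ndarray:
    """Express a full-resolution row-vector affine on a shrunk lattice."""
    d = matrix.shape[0] - 1
    m = matrix.copy()
    m[d, :d] = m[d, :d] / factor
    return m


def register_affine(fixed: FeatureImage, moving: FeatureImage,
                    cfg: RegistrationConfig | None = None) -> AffineTransform:
    """Estimate a 12-parameter (6 in 2D) affine maximizing channel similarity.

    The SSD metric is optimized coarse-to-fine with L-BFGS using an analytic
    gradient; the MI metric falls back to derivative-free Powell search.
    The returned matrix maps FIXED-space voxel coordinates to MOVING-space
    voxel coordinates (pull-back), ready for :func:`apply_transform_lowres`.
    """
    cfg = cfg or RegistrationConfig()
    if list(fixed.region_ids) != list(moving.region_ids):
        raise ValidationError("fixed and moving must encode the same region list")
    d = fixed.ndim
    p = np.zeros(d * d + d)  # matrix = I + dA, then translation

    def build(pvec):
        m = np.eye(d + 1)
        m[:d, :d] += pvec[: d * d].reshape(d, d)
        m[d, :d] = pvec[d * d:]
        return m

    for level in cfg.levels:
        F = _downsample_channels(fixed.channels, level).astype(np.float64)
        M = _downsample_channels(moving.channels, level).astype(np.float64)
        grid = fields.identity_grid(F.shape[1:]).reshape(d, -1).T  # (N, d)

        if cfg.metric == "mi":
            def cost_mi(pvec):
                m = _level_matrix(build(pvec), level)
                total = 0.0
                for c in range(F.shape[0]):
                    w = fields.warp_affine_image(M[c], m, out_shape=F.shape[1:],
                                                 mode="nearest")
                    total -= _mutual_information(F[c], w)
                return total
            res = optimize.minimize(cost_mi, p, method="Powell",
                                    options={"maxiter": cfg.affine_maxiter})
            p = res.x
            continue

        def cost_grad(pvec):
            m = _level_matrix(build(pvec), level)
            A = m[:d, :d]
            Ainv = np.linalg.inv(A)
            total = 0.0
            gA = np.zeros((d, d))
            gt = np.zeros(d)
            n = grid.shape[0]
            for c in range(F.shape[0]):
                # clamped sampling keeps the metric continuous at the border
                w = fields.warp_affine_image(M[c], m, out_shape=F.shape[1:],
                                             mode="nearest")
                diff = w - F[c]
                total += float((diff ** 2).mean())
                gq = np.stack(np.gradient(w)).reshape(d, -1)       # grad in fixed frame
                gsrc = Ainv @ gq                                   # grad in source frame
                dg = diff.reshape(1, -1) * gsrc                    # (d, N)
                gA += (grid.T @ dg.T) * (2.0 / n)                  # dE/dA[i,j]
                gt += dg.sum(axis=1) * (2.0 / n)
            gt_full = gt / level  # translation parameter is in full-res voxels
            return total, np.concatenate([gA.ravel(), gt_full])

        res = optimize.minimize(cost_grad, p, jac=True, method="L-BFGS-B",
                                options={"maxiter": cfg.affine_maxiter})
        p = res.x

    matrix = build(p)
    final = AffineTransform(matrix)
    # degenerate-overlap guard: the warped moving must carry some signal
    w = np.stack([
        fields.warp_affine_image(c.astype(np.float64), matrix, out_shape=fixed.spatial_shape)
        for c in moving.channels
    ])
    if float(np.abs(moving.channels).max()) > 0 and float(np.abs(w).max()) == 0.0:
        raise ConvergenceError("affine registration found no image overlap")
    return final


# ---------------------------------------------------------------------------
# diffeomorphic stage

def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _demons_update(F, Mw, alpha2):
    """Multi-channel demons force: (d, *spatial) update toward F."""
    d = F.ndim - 1
    num = np.zeros((d,) + F.shape[1:])
    den = np.zeros(F.shape[1:])
    for c in range(F.shape[0]):
        diff = F[c] - Mw[c]
        g = np.stack(np.gradient(Mw[c]))
        num += diff * g
        den += (g ** 2).sum(axis=0) + alpha2 * diff ** 2
    return num / np.maximum(den, 1e-12)


def _demons_level(F, M, v, cfg: RegistrationConfig, iters: int, trace: list):
    step = cfg.step
    alpha2 = 1.0 / (cfg.step ** 2)
    u = fields.exp_field(v)
    uinv = fields.exp_field(-v)
    Mw = np.stack([fields.warp_image(M[c], u) for c in range(M.shape[0])])
    Fw = np.stack([fields.warp_image(F[c], uinv) for c in range(F.shape[0])])
    energy = _ssd(Mw, F) + _ssd(Fw, M)
    trace.append(energy)
    rejects = 0
    for _ in range(int(iters)):
        df = _demons_update(F, Mw, alpha2)    # drives exp(v): moving -> fixed
        db = _demons_update(M, Fw, alpha2)    # drives exp(-v): fixed -> moving
        delta = 0.5 * (df - db)
        delta = fields.smooth_field(delta, cfg.update_sigma)
        norm = np.sqrt((delta ** 2).sum(axis=0))
        peak = float(norm.max())
        if peak <= 1e-12:
            break
        accepted = False
        while step > 1e-3:
            scaled = delta * min(1.0, step / peak)
            v_prop = fields.smooth_field(v + scaled, cfg.field_sigma)
            u_p = fields.exp_field(v_prop)
            uinv_p = fields.exp_field(-v_prop)
            Mw_p = np.stack([fields.warp_image(M[c], u_p) for c in range(M.shape[0])])
            Fw_p = np.stack([fields.warp_image(F[c], uinv_p) for c in range(F.shape[0])])
            e_prop = _ssd(Mw_p, F) + _ssd(Fw_p, M)
            if e_prop <= energy:
                v, u, uinv, Mw, Fw, energy = v_prop, u_p, uinv_p, Mw_p, Fw_p, e_prop
                trace.append(energy)
                step = min(step * 1.2, cfg.step)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            rejects += 1
            if rejects > cfg.patience:
                break
        else:
            rejects = 0
    return v


def register_diffeomorphic(fixed: FeatureImage, moving: FeatureImage,
                           init: AffineTransform | None = None,
                           cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Symmetric diffeomorphic registration of feature images.

    The moving channels are first resampled through ``init`` (identity when
    omitted); a stationary velocity field is then optimized coarse-to-fine
    with symmetric demons-like forces, accepting only energy-non-increasing
    steps.  Returns the linear matrix together with the forward (``phi1``)
    and inverse (``phi2``) displacement fields.
    """
    cfg = cfg or RegistrationConfig()
    if list(fixed.region_ids) != list(moving.region_ids):
        raise ValidationError("fixed and moving must encode the same region list")
    d = fixed.ndim
    init = init or AffineTransform.identity(d)
    if init.ndim != d:
        raise ValidationError("init affine dimensionality mismatch")

    F = fixed.channels.astype(np.float64)
    if np.allclose(init.matrix, np.eye(d + 1)):
        M = moving.channels.astype(np.float64)
    else:
        M = np.stack([
            fields.warp_affine_image(c.astype(np.float64), init.matrix,
                                     out_shape=fixed.spatial_shape)
            for c in moving.channels
        ])
    if M.shape != F.shape:
        raise ValidationError("fixed and moving lattices differ after affine prealignment")

    trace: list[float] = []
    v = None
    for level, iters in zip(cfg.levels, cfg.iters_per_level):
        Fl = _downsample_channels(F, level)
        Ml = _downsample_channels(M, level)
        if v is None:
            v = np.zeros((d,) + Fl.shape[1:])
        else:
            v = _upsample_field(v, Fl.shape[1:])
        v = _demons_level(Fl, Ml, v, cfg, iters, trace)
    v = _upsample_field(v, F.shape[1:])

    u = fields.exp_field(v)        # pull-back in the prealigned frame
    uinv = fields.exp_field(-v)    # forward (push) in the prealigned frame
    # fold the affine's linear part into phi2 so that
    # apply_transform_lowres(moving, M, phi2) == warp(prealigned_moving, u)
    A = init.linear
    phi2 = np.einsum("i...,ij->j...", u, A)
    return RegistrationResult(
        M=init,
        phi1=DisplacementField(uinv.astype(np.float32)),
        phi2=DisplacementField(phi2.astype(np.float32)),
        energy_trace=trace,
    )


# ---------------------------------------------------------------------------
# field algebra on the public type

def compose_fields(f: DisplacementField, g: DisplacementField) -> DisplacementField:
    """``(f o g)(x) = g(x) + f(x + g(x))`` with n-linear sampling of ``f``."""
    if f.shape != g.shape:
        raise ValidationError(f"field lattices differ: {f.shape} vs {g.shape}")
    return DisplacementField(fields.compose(np.asarray(f.components, dtype=np.float64),
                                            np.asarray(g.components, dtype=np.float64)))


def invert_field(f: DisplacementField, iters: int = 50, tol: float = 0.05) -> DisplacementField:
    """Fixed-point inverse of a small smooth field; warns if above ``tol``."""
    g, residual = fields.invert(np.asarray(f.components, dtype=np.float64),
                                iters=iters, tol=tol)
    if residual > tol:
        warnings.warn(
            f"field inversion residual {residual:.3g} voxels exceeds tol {tol}",
            RuntimeWarning,
        )
    out = DisplacementField(g)
    out.residual = residual
    return out


def apply_transform_lowres(v, M: AffineTransform | None = None,
                           field: DisplacementField | None = None,
                           interp: str | None = None):
    """Pull-back resampling at one resolution: ``out(q) = v([q] @ M + field(q))``.

    Linear interpolation for gray volumes, nearest for label volumes (so the
    output label set is a subset of the input's).  A plain array of any
    dimensionality is also accepted (nearest if integer-typed unless
    ``interp`` overrides) and returned as an array.  This operation is the
    ORACLE against which block-wise high-resolution warping is tested.
    """
    is_labels = isinstance(v, LabelVolume)
    is_array = not is_labels and not isinstance(v, Volume3D)
    if is_array:
        data = np.asarray(v)
        if interp is None:
            interp = "nearest" if np.issubdtype(data.dtype, np.integer) else "linear"
    else:
        data = v.labels if is_labels else v.data
    d = data.ndim
    if interp is None:
        interp = "nearest" if is_labels else "linear"
    M = M or AffineTransform.identity(d)
    grid = fields.identity_grid(data.shape).reshape(d, -1).T
    src = grid @ M.linear + M.translation
    if field is not None:
        src = src + np.asarray(field.components, dtype=np.float64).reshape(d, -1).T
    coords = src.T
    if interp == "nearest":
        out = fields.nearest_sample(data, coords, fill=0).reshape(data.shape)
    else:
        out = fields.trilinear_sample(data, coords, fill=0.0).reshape(data.shape)
        if np.issubdtype(data.dtype, np.integer):
            info = np.iinfo(data.dtype)
            out = np.clip(np.rint(out), info.min, info.max)
        out = out.astype(data.dtype)
    if is_array:
        return out.astype(data.dtype)
    if is_labels:
        return LabelVolume(out.astype(data.dtype), dict(v.names), v.voxel_size)
    return Volume3D(out, v.voxel_size)
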