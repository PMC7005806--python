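"""Warping vectorized datasets (SWC neurons, cell positions, centerlines).

Images are resampled by pull-back, but point sets push FORWARD: a point at
moving-space coordinate ``P`` (high resolution) maps through the inverse of
the image mapping.  With the low-resolution registration outputs ``(M,
phi1, s)`` where ``phi1`` is the forward/direct field, the map is

    p = P / s                       (to the low-res lattice)
    q = [p] @ M^-1                  (undo the pull-back affine)
    P_fixed = s * (q + phi1(q))     (forward displacement, back to high res)

which is the forward analogue of the high-resolution voxel mapping.  The
duality with image warping (inverse field, pull-back) is covered by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import AffineTransform, DisplacementField, LabelVolume, SWCNeuron, ValidationError
from .volume_transform import _as_scale_triple, interp_field

__all__ = [
    "PointSet",
    "ProjectionPattern",
    "transform_points",
    "transform_swc",
    "projection_pattern",
]


@dataclass
class PointSet:
    """N points with a declared coordinate unit ('voxel' or 'um')."""

    coords: np.ndarray
    unit: str = "voxel"
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3:
            raise ValidationError("PointSet coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("PointSet coords must be finite")
        if self.unit not in ("voxel", "um"):
            raise ValidationError(f"unknown unit {self.unit!r}")


def _forward_map(coords: np.ndarray, M: AffineTransform | None,
                 field_forward: DisplacementField | None, s) -> np.ndarray:
    s = np.asarray(_as_scale_triple(s))
    p = np.atleast_2d(np.asarray(coords, dtype=float)) / s
    q = M.inverse().apply(p) if M is not None else p
    if field_forward is not None:
        q = q + interp_field(field_forward, q)
    return q * s


def transform_points(p: PointSet, M: AffineTransform | None = None,
                     field_forward: DisplacementField | None = None,
                     s=1.0) -> PointSet:
    """Push a point set from moving space into fixed space.

    Points must be in voxel units of the high-resolution moving lattice
    (convert micrometre data by dividing by the voxel size first).  Points
    whose low-res coordinate falls outside the forward field's lattice are
    still mapped — the field interpolation clamps — and counted in a
    warning.
    """
    if p.unit != "voxel":
        raise ValidationError("transform_points expects voxel-unit coordinates; "
                              "convert um coordinates by the source voxel size first")
    s3 = np.asarray(_as_scale_triple(s))
    if field_forward is not None:
        low = p.coords / s3
        shape = np.asarray(field_forward.shape)
        outside = np.any((low < 0) | (low > shape - 1), axis=1)
        if outside.any():
            warnings.warn(f"{int(outside.sum())} points outside the field lattice "
                          "(mapped with clamped displacements)", RuntimeWarning)
    out = _forward_map(p.coords, M, field_forward, s)
    return PointSet(out, "voxel", None if p.labels is None else p.labels.copy())


def transform_swc(n: SWCNeuron, M: AffineTransform | None = None,
                  field_forward: DisplacementField | None = None,
                  s=1.0) -> SWCNeuron:
    """Map a traced neuron into fixed space; topology is untouched.

    Node radii are rescaled by the isotropic scale of the affine-only part
    of the map, ``|det A^-1|^(1/3)`` (the field's local Jacobian is ignored
    for radii).
    """
    pts = PointSet(n.coords, "voxel")
    out = transform_points(pts, M, field_forward, s)
    radii = n.nodes["radius"].to_numpy(dtype=float)
    if M is not None:
        radii = radii * float(abs(np.linalg.det(M.linear))) ** (-1.0 / 3.0)
    return n.with_coords(out.coords, radii)


@dataclass
class ProjectionPattern:
    """Per-region node counts and cable length of one neuron."""

    node_counts: dict      # region name -> count (background included as 'background')
    cable_length: dict     # region name -> um
    total_nodes: int
    total_length: float
    step: float            # um, segment subdivision step used


def _region_at(annotation: LabelVolume, xyz: np.ndarray) -> np.ndarray:
    """Label id at physical positions (um); outside volume -> -1."""
    vs = np.asarray(annotation.voxel_size)
    idx = np.floor(np.atleast_2d(xyz) / vs).astype(int)
    shape = np.asarray(annotation.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.full(len(idx), -1, dtype=int)
    if inside.any():
        ii = idx[inside]
        out[inside] = annotation.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def projection_pattern(n: SWCNeuron, annotation: LabelVolume) -> ProjectionPattern:
    """Count nodes and accumulate cable length per annotated region.

    Node coordinates are in micrometres of the annotation space.  Cable
    length is accumulated by subdividing each parent-child segment at steps
    of the smallest voxel size and assigning each sub-segment to the region
    under its midpoint.
    """
    names = dict(annotation.names)
    names[0] = names.get(0, "background")

    def name_of(lab: int) -> str:
        return "background" if lab <= 0 else names.get(lab, f"label_{lab}")

    regions = _region_at(annotation, n.coords)
    if np.any(regions < 0):
        warnings.warn(f"{int((regions < 0).sum())} neuron nodes outside the annotation "
                      "bounds (counted as background)", RuntimeWarning)
    counts: dict[str, int] = {}
    for lab in regions:
        key = name_of(lab)
        counts[key] = counts.get(key, 0) + 1

    step = float(min(annotation.voxel_size))
    lengths: dict[str, float] = {}
    total = 0.0
    for a, b in n.segments():
        seg_len = float(np.linalg.norm(b - a))
        total += seg_len
        if seg_len == 0.0:
            continue
        k = max(1, int(np.ceil(seg_len / step)))
        t = (np.arange(k) + 0.5) / k
        mids = a[None, :] + t[:, None] * (b - a)[None, :]
        labs = _region_at(annotation, mids)
        piece = seg_len / k
        for lab in labs:
            key = name_of(lab)
            lengths[key] = lengths.get(key, 0.0) + piece
    return ProjectionPattern(counts, lengths, int(len(n.nodes)), total, step)
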