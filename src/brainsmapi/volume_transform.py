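"""Block-wise application of a low-resolution transform to a full-resolution volume.

The registration stage yields a linear matrix and displacement fields on a
coarse (e.g. 10 um) lattice.  Rather than upsampling the field to full
resolution (which for teravoxel data would itself be teravoxel-sized), the
output space is tiled into blocks and, for every output voxel ``P`` at high
resolution:

1. the affine is rescaled once: ``M' = diag(1/s) . M . diag(s)``, so that
   ``[P] @ M' = s * ([P/s] @ M)`` exactly;
2. the coarse field is sampled on the fly by trilinear interpolation over
   the 8 surrounding lattice vectors;
3. the source coordinate is ``P'' = [P] @ M' + s * phi(P/s)`` and the source
   volume is sampled there (pull-back, so no holes can appear).

Per block, the needed source region (ROI) is found by mapping all points on
the block's six surfaces and padding by a safety margin; only the source
blocks overlapping that ROI are read.  Blocks are pure functions of
``(extent, source, mapping)``, so any worker count or execution order gives
bit-identical output, and blocks whose ROI misses the brain mask can be
skipped outright.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile

from . import fields
from .io_formats import BlockStore, read_block, write_block
from .types import AffineTransform, DisplacementField, ValidationError, Volume3D

__all__ = [
    "HighResMapping",
    "BlockGrid",
    "TransformStats",
    "scale_affine",
    "interp_field",
    "map_point",
    "plan_blocks",
    "roi_for_block",
    "transform_block",
    "transform_volume",
    "transform_volume_dense",
    "reslice",
]


def _as_scale_triple(s) -> tuple[float, float, float]:
    if np.isscalar(s):
        s = (float(s),) * 3
    s = tuple(float(v) for v in s)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValidationError(f"scale factor must be positive (scalar or triple), got {s}")
    return s


def scale_affine(M: AffineTransform, s) -> AffineTransform:
    """Rescale a low-resolution affine to high resolution.

    Under the row-vector convention the shrink matrix acts first and the
    amplification last: ``M' = diag(1/s,1) . M . diag(s,1)``, which gives the
    defining property ``[s*p] @ M' = s * ([p] @ M)`` for every point ``p``.
    """
    s = _as_scale_triple(s)
    shrink = np.diag([1.0 / s[0], 1.0 / s[1], 1.0 / s[2], 1.0])
    amp = np.diag([s[0], s[1], s[2], 1.0])
    return AffineTransform(shrink @ M.matrix @ amp)


@dataclass
class HighResMapping:
    """Everything needed to map a high-res output voxel to its source coordinate."""

    M_prime: AffineTransform
    field: DisplacementField
    s: tuple[float, float, float]
    out_shape: tuple[int, int, int]

    def __post_init__(self):
        self.s = _as_scale_triple(self.s)
        self.out_shape = tuple(int(v) for v in self.out_shape)

    @classmethod
    def from_lowres(cls, M: AffineTransform, field: DisplacementField, s,
                    out_shape) -> "HighResMapping":
        """Build the high-res mapping from registration outputs at low res."""
        return cls(scale_affine(M, s), field, _as_scale_triple(s), tuple(out_shape))


def interp_field(field: DisplacementField, q: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the displacement lattice at points ``q``.

    ``q`` is an ``(N, 3)`` array of continuous low-resolution coordinates;
    out-of-lattice queries clamp to the boundary cells.  Returns ``(N, 3)``
    displacement vectors in low-resolution voxel units.
    """
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if q.shape[-1] != field.ndim:
        raise ValidationError(f"query points must be (N, {field.ndim})")
    if not np.all(np.isfinite(q)):
        raise ValidationError("query points contain NaN/inf")
    coords = q.T
    comps = np.asarray(field.components, dtype=np.float64)
    return np.stack(
        [fields.trilinear_sample(comps[d], coords, mode="clamp") for d in range(field.ndim)],
        axis=-1,
    )


def map_point(m: HighResMapping, P: np.ndarray) -> np.ndarray:
    """Map high-res output coordinates ``P`` to high-res source coordinates.

    ``P' = [P] @ M'`` then ``P'' = P' + s * phi(P / s)`` componentwise.
    Vectorized over an ``(N, 3)`` array.
    """
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    s = np.asarray(m.s)
    Pp = m.M_prime.apply(P)
    disp = interp_field(m.field, P / s)
    return Pp + s * disp


@dataclass
class BlockGrid:
    """Half-open tiling of the output space into blocks."""

    out_shape: tuple[int, int, int]
    block_size: tuple[int, int, int]

    def __post_init__(self):
        self.out_shape = tuple(int(v) for v in self.out_shape)
        if isinstance(self.block_size, int):
            self.block_size = (self.block_size,) * 3
        self.block_size = tuple(int(v) for v in self.block_size)
        if any(b < 8 for b in self.block_size):
            raise ValidationError(f"block_size must be >= 8 per axis, got {self.block_size}")

    @property
    def n_blocks(self) -> tuple[int, int, int]:
        return tuple(-(-s // b) for s, b in zip(self.out_shape, self.block_size))

    def extent(self, idx) -> tuple[tuple[int, int], ...]:
        return tuple(
            (i * b, min((i + 1) * b, s))
            for i, b, s in zip(idx, self.block_size, self.out_shape)
        )

    def __iter__(self):
        """Iterate indices row-major: i outermost, k innermost."""
        ni, nj, nk = self.n_blocks
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    yield (i, j, k)


def plan_blocks(out_shape, block_size) -> BlockGrid:
    return BlockGrid(tuple(out_shape), block_size)


@dataclass
class TransformStats:
    blocks_total: int = 0
    blocks_skipped: int = 0
    src_blocks_loaded: dict = dc_field(default_factory=dict)  # n_roi_blocks -> count
    max_roi_blocks: int = 0
    containment_violations: int = 0

    def record(self, n_roi_blocks: int, skipped: bool, violations: int = 0):
        self.blocks_total += 1
        if skipped:
            self.blocks_skipped += 1
        self.src_blocks_loaded[n_roi_blocks] = self.src_blocks_loaded.get(n_roi_blocks, 0) + 1
        self.max_roi_blocks = max(self.max_roi_blocks, n_roi_blocks)
        self.containment_violations += violations


def _face_points(extent, dense_limit: int = 64) -> np.ndarray:
    """All points on the six surfaces of a block (stride-2 plus edges when large)."""
    axes = []
    large = any(hi - lo > dense_limit for lo, hi in extent)
    for lo, hi in extent:
        stride = 2 if large else 1
        vals = np.arange(lo, hi, stride)
        if vals[-1] != hi - 1:
            vals = np.append(vals, hi - 1)
        axes.append(vals)
    pts = []
    for a in range(3):
        for bound_idx in (0, extent[a][1] - 1 - extent[a][0]):
            sel = [axes[0], axes[1], axes[2]]
            sel[a] = np.asarray([extent[a][0] + bound_idx])
            g = np.meshgrid(*sel, indexing="ij")
            pts.append(np.stack([c.ravel() for c in g], axis=1))
    return np.unique(np.concatenate(pts, axis=0), axis=0).astype(np.float64)


def default_margin(s) -> int:
    """Safety padding of the six-surface ROI, 2 source voxels per unit scale."""
    return int(np.ceil(2 * max(_as_scale_triple(s))))


def roi_for_block(block_extent, m: HighResMapping, margin: int | None = None,
                  src_shape=None, src_block_size=None):
    """Source-space ROI of one output block via six-surface mapping.

    Returns ``(roi_extent, src_block_indices)`` where ``roi_extent`` is a
    half-open, margin-padded bounding box clipped to the source extent (or
    ``None`` when the block maps entirely outside the source), and the index
    set lists overlapped source blocks when ``src_block_size`` is given.
    """
    if margin is None:
        margin = default_margin(m.s)
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    pts = _face_points(tuple(tuple(int(v) for v in e) for e in block_extent))
    mapped = map_point(m, pts)
    lo = np.floor(mapped.min(axis=0)).astype(int) - margin
    hi = np.ceil(mapped.max(axis=0)).astype(int) + 1 + margin
    if src_shape is not None:
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(src_shape, dtype=int))
        if np.any(lo >= hi):
            return None, set()
    roi = tuple((int(a), int(b)) for a, b in zip(lo, hi))
    indices = set()
    if src_block_size is not None:
        if np.isscalar(src_block_size):
            b = (int(src_block_size),) * 3
        else:
            b = tuple(int(v) for v in src_block_size)
        ranges = [range(roi[a][0] // b[a], (roi[a][1] - 1) // b[a] + 1) for a in range(3)]
        indices = {(i, j, k) for i in ranges[0] for j in ranges[1] for k in ranges[2]}
    return roi, indices


def _sample_source(data: np.ndarray, coords: np.ndarray, interp: str, fill,
                   offset=(0, 0, 0)) -> np.ndarray:
    """Sample ``data`` at ``coords`` (3, N) minus an exact integer ``offset``.

    Integer offsets subtract exactly in float64, so sampling a cropped ROI
    is arithmetically identical to sampling the full volume.
    """
    local = np.stack([coords[a] - float(offset[a]) for a in range(3)])
    if interp == "nearest":
        return fields.nearest_sample(data, local, fill=fill)
    out = fields.trilinear_sample(data, local, fill=float(fill))
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(data.dtype)


def _block_coords(extent) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(lo, hi, dtype=np.float64) for lo, hi in extent],
                        indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _transform_block_impl(block_extent, src: BlockStore, m: HighResMapping,
                          interp: str, brain_mask, margin):
    shape = tuple(hi - lo for lo, hi in block_extent)
    fill = src.fill_value
    roi, roi_idx = roi_for_block(block_extent, m, margin=margin,
                                 src_shape=src.shape, src_block_size=src.block_size)
    if roi is None:
        return np.full(shape, fill, dtype=src.dtype), {"skipped": True, "n_roi": 0,
                                                       "violations": 0}
    if brain_mask is not None:
        s = np.asarray(m.s)
        mlo = np.floor(np.asarray([roi[a][0] for a in range(3)]) / s).astype(int)
        mhi = np.ceil(np.asarray([roi[a][1] for a in range(3)]) / s).astype(int)
        mlo = np.maximum(mlo, 0)
        mhi = np.minimum(mhi, np.asarray(brain_mask.shape))
        sub = brain_mask[mlo[0]:mhi[0], mlo[1]:mhi[1], mlo[2]:mhi[2]]
        if sub.size == 0 or not np.any(sub):
            return np.full(shape, fill, dtype=src.dtype), {"skipped": True,
                                                           "n_roi": len(roi_idx),
                                                           "violations": 0}
    data = src.read_region(roi)
    pts = _block_coords(block_extent)
    mapped = map_point(m, pts).T  # (3, N)
    # containment accounting: inside the source but outside the padded ROI
    in_src = np.ones(mapped.shape[1], dtype=bool)
    in_roi = np.ones(mapped.shape[1], dtype=bool)
    for a in range(3):
        in_src &= (mapped[a] >= 0) & (mapped[a] <= src.shape[a] - 1)
        in_roi &= (mapped[a] >= roi[a][0]) & (mapped[a] <= roi[a][1] - 1)
    violations = int(np.count_nonzero(in_src & ~in_roi))
    out = _sample_source(data, mapped, interp, fill,
                         offset=[roi[a][0] for a in range(3)])
    return out.reshape(shape), {"skipped": False, "n_roi": len(roi_idx),
                                "violations": violations}


def transform_block(block_extent, src: BlockStore, m: HighResMapping,
                    interp: str = "linear", brain_mask=None,
                    margin: int | None = None) -> np.ndarray:
    """Warp one output block by pull-back sampling of its source ROI."""
    data, _info = _transform_block_impl(block_extent, src, m, interp, brain_mask, margin)
    return data


def transform_volume(src: BlockStore, m: HighResMapping, out: BlockStore,
                     interp: str = "linear", workers: int = 1, brain_mask=None,
                     margin: int | None = None) -> TransformStats:
    """Warp every output block; pure per-block contract, any worker count.

    Emits a counted warning in the stats if any source sample escapes its
    block's padded ROI (never silent corruption).
    """
    if tuple(out.shape) != tuple(m.out_shape):
        raise ValidationError(f"output store shape {out.shape} != mapping out_shape {m.out_shape}")
    grid = plan_blocks(m.out_shape, out.block_size)
    stats = TransformStats()

    def job(idx):
        extent = grid.extent(idx)
        data, info = _transform_block_impl(extent, src, m, interp, brain_mask, margin)
        return idx, data, info

    indices = list(grid)
    if workers <= 1:
        results = map(job, indices)
        for idx, data, info in results:
            write_block(out, idx, data)
            stats.record(info["n_roi"], info["skipped"], info["violations"])
    else:
        with ThreadPoolExecutor(max_workers=int(workers)) as ex:
            for idx, data, info in ex.map(job, indices):
                write_block(out, idx, data)
                stats.record(info["n_roi"], info["skipped"], info["violations"])
    return stats


def transform_volume_dense(src: Volume3D, m: HighResMapping,
                           interp: str = "linear") -> Volume3D:
    """Direct whole-volume warp (no blocking): the reference implementation.

    Identical sampling arithmetic to :func:`transform_block`; used as the
    equivalence oracle for the block-wise path.
    """
    pts = _block_coords(tuple((0, s) for s in m.out_shape))
    mapped = map_point(m, pts).T
    out = _sample_source(src.data, mapped, interp, 0)
    return Volume3D(out.reshape(m.out_shape), src.voxel_size)


_AXIS = {"x": 0, "y": 1, "z": 2}


def reslice(store: BlockStore, axis: str, out_dir) -> list[Path]:
    """Write the 2D slice sequence along an anatomical axis.

    Slice ``k`` of axis ``z`` holds volume voxels ``(a, b, k)`` at pixel
    ``(a, b)`` (array row = first remaining axis).  Files are numbered with
    zero-padded indices; restacking them reproduces the volume bit-exactly.
    """
    if axis not in _AXIS:
        raise ValidationError(f"axis must be one of x|y|z, got {axis!r}")
    a = _AXIS[axis]
    missing = [idx for idx in store.iter_indices() if not store._block_path(idx).exists()]
    if missing:
        shown = ", ".join(str(i) for i in missing[:10])
        raise IOError(f"block store incomplete; {len(missing)} missing blocks: {shown}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = store.shape[a]
    width = max(5, len(str(n)))
    paths = []
    for k in range(n):
        extent = [(0, store.shape[0]), (0, store.shape[1]), (0, store.shape[2])]
        extent[a] = (k, k + 1)
        sl = store.read_region(extent).squeeze(axis=a)
        p = out_dir / f"slice_{k:0{width}d}.tif"
        tifffile.imwrite(p, np.ascontiguousarray(sl))
        paths.append(p)
    return paths
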