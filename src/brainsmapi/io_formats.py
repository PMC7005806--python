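"""Readers and writers for every on-disk artifact the pipeline touches.

Dialects
--------
* **Volumes** — either a directory of lexicographically ordered 2D TIFF
  z-slices (pixel rows = y, columns = x, so x is the fastest-varying index on
  disk) or a single NIfTI-1 file.  In memory a volume is indexed
  ``data[x, y, z]``.
* **Affines** — plain text, one comment header line documenting the
  row-vector convention, then 4 lines of 4 numbers at 17 significant digits.
* **Displacement fields** — one 4D TIFF or NIfTI whose LAST axis holds the
  three components in the fixed order (phi_x, phi_y, phi_z).
* **Block store** — a directory holding ``meta.json`` plus one 3D TIFF per
  block, named ``block_i_j_k.tif`` with half-open extents
  ``[i*bx, min((i+1)*bx, X))`` etc.  Absent blocks read as ``fill_value``.
* **SWC** — the standard 7-column text format; ``#`` comment lines are
  dropped on read (documented).
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import nibabel as nib
import pandas as pd
import tifffile

from .types import (
    AffineTransform,
    DisplacementField,
    FormatError,
    SWCNeuron,
    ValidationError,
    Volume3D,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
    "read_field",
    "write_field",
    "read_swc",
    "write_swc",
    "BlockStore",
    "create_block_store",
    "open_block_store",
    "read_block",
    "write_block",
    "ingest_volume",
    "assemble_volume",
]


# ---------------------------------------------------------------------------
# volumes

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.is_dir():
        return "tiff-stack"
    if path.suffix in (".nii", ".gz"):
        return "nifti"
    if path.suffix in (".tif", ".tiff"):
        return "tiff"
    raise FormatError(f"cannot infer volume format for {path}")


def read_volume(path, format: str | None = None, voxel_size=None) -> Volume3D:
    """Read a 3D volume from a TIFF slice stack, a 3D TIFF, or a NIfTI file.

    ``voxel_size`` overrides any metadata (required for TIFF stacks, which
    carry none in this dialect; defaults to 1 um isotropic).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such volume: {path}")
    fmt = _infer_format(path, format)
    if fmt == "tiff-stack":
        slices = sorted(p for p in path.iterdir() if p.suffix in (".tif", ".tiff"))
        if not slices:
            raise FormatError(f"no TIFF slices in {path}")
        planes = [tifffile.imread(s) for s in slices]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1 or planes[0].ndim != 2:
            raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        # slice arrays are (y, x); stack along z then reorder to (x, y, z)
        data = np.stack(planes, axis=0).transpose(2, 1, 0)
        return Volume3D(data, voxel_size or (1.0, 1.0, 1.0))
    if fmt == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise FormatError(f"expected 3D TIFF, got ndim={arr.ndim}")
        return Volume3D(arr.transpose(2, 1, 0), voxel_size or (1.0, 1.0, 1.0))
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"expected 3D NIfTI, got ndim={data.ndim}")
        vs = voxel_size or tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume3D(data, vs)
    raise FormatError(f"unknown volume format {fmt!r}")


def write_volume(v: Volume3D, path, format: str | None = None) -> None:
    """Write a volume; round-trips bit-identically with :func:`read_volume`."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "nifti" if path.suffix in (".nii", ".gz") else ("tiff" if path.suffix else "tiff-stack")
    if fmt == "tiff-stack":
        path.mkdir(parents=True, exist_ok=True)
        nz = v.shape[2]
        width = max(4, len(str(nz)))
        for k in range(nz):
            tifffile.imwrite(path / f"z{k:0{width}d}.tif", v.data[:, :, k].T)
        return
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        tifffile.imwrite(path, np.ascontiguousarray(v.data.transpose(2, 1, 0)))
        return
    if fmt == "nifti":
        aff = np.diag(list(v.voxel_size) + [1.0])
        img = nib.Nifti1Image(np.asarray(v.data), aff)
        img.header.set_zooms(v.voxel_size)
        nib.save(img, str(path))
        return
    raise FormatError(f"unknown volume format {fmt!r}")


# ---------------------------------------------------------------------------
# affines

_AFFINE_HEADER = "# row-vector affine: [x y z 1] @ M ; rows are matrix rows"


def write_affine(m: AffineTransform, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_AFFINE_HEADER + "\n")
        for row in m.matrix:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def read_affine(path) -> AffineTransform:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(t) for t in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (4, 4) and arr.shape != (3, 3):
        raise FormatError(f"affine file must hold a 4x4 (or 3x3) matrix, got {arr.shape}")
    return AffineTransform(arr)  # validates invertibility / last column


# ---------------------------------------------------------------------------
# displacement fields

def write_field(f: DisplacementField, path) -> None:
    """Write a 3-component field as a 4D file (last axis = components)."""
    if f.ndim != 3:
        raise ValidationError("only 3D fields are written to disk")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stacked = np.moveaxis(np.asarray(f.components, dtype=np.float32), 0, -1)  # (x,y,z,3)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(stacked.transpose(2, 1, 0, 3)))
    else:
        nib.save(nib.Nifti1Image(stacked, np.eye(4)), str(path))


def read_field(path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such field: {path}")
    if path.suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 4:
            raise FormatError(f"field file must be 4D, got ndim={arr.ndim}")
        arr = arr.transpose(2, 1, 0, 3)
    else:
        arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise FormatError(f"field file must have 3 channels on the last axis, got {arr.shape}")
    return DisplacementField(np.moveaxis(arr, -1, 0))


# ---------------------------------------------------------------------------
# SWC

def read_swc(path) -> SWCNeuron:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such SWC file: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"SWC lines must have 7 columns, got {len(parts)}: {line!r}")
            rows.append(
                [int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), int(parts[6])]
            )
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    return SWCNeuron(df)


def write_swc(n: SWCNeuron, path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for _, r in n.nodes.iterrows():
            fh.write(
                f"{int(r['id'])} {int(r['type'])} {r['x']:.6f} {r['y']:.6f} "
                f"{r['z']:.6f} {r['radius']:.6f} {int(r['parent'])}\n"
            )


# ---------------------------------------------------------------------------
# block store

@dataclass
class BlockStore:
    """A directory of per-block 3D TIFFs plus one JSON metadata record.

    Blocks are addressed by an integer index triple ``(i, j, k)`` covering
    the half-open extent ``[i*bx, min((i+1)*bx, X)) x ... ``.  Interior
    blocks have exactly ``block_size`` shape; edge blocks are trimmed.
    Reading an absent block returns a ``fill_value``-filled block.
    """

    root: Path
    shape: tuple[int, int, int]
    block_size: tuple[int, int, int]
    dtype: np.dtype
    voxel_size: tuple[float, float, float]
    fill_value: float = 0.0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(-(-s // b) for s, b in zip(self.shape, self.block_size))

    def block_extent(self, idx) -> tuple[tuple[int, int], ...]:
        """Half-open per-axis extent of block ``idx``."""
        self._check_idx(idx)
        return tuple(
            (i * b, min((i + 1) * b, s))
            for i, b, s in zip(idx, self.block_size, self.shape)
        )

    def block_shape(self, idx) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.block_extent(idx))

    def _check_idx(self, idx):
        if len(idx) != 3:
            raise IndexError(f"block index must be a triple, got {idx}")
        for i, g in zip(idx, self.grid_shape):
            if not (0 <= i < g):
                raise IndexError(f"block index {tuple(idx)} outside grid {self.grid_shape}")

    def _block_path(self, idx) -> Path:
        return self.root / f"block_{idx[0]}_{idx[1]}_{idx[2]}.tif"

    def iter_indices(self) -> Iterator[tuple[int, int, int]]:
        """Yield block indices in row-major (i, j, k) order, k innermost."""
        gi, gj, gk = self.grid_shape
        for i in range(gi):
            for j in range(gj):
                for k in range(gk):
                    yield (i, j, k)

    # -- region access ------------------------------------------------------
    def read_region(self, extent) -> np.ndarray:
        """Assemble an arbitrary half-open ``((x0,x1),(y0,y1),(z0,z1))`` region.

        The region is clipped against the store; voxels outside come back as
        ``fill_value``.
        """
        (x0, x1), (y0, y1), (z0, z1) = [(int(a), int(b)) for a, b in extent]
        out = np.full((x1 - x0, y1 - y0, z1 - z0), self.fill_value, dtype=self.dtype)
        cx0, cx1 = max(x0, 0), min(x1, self.shape[0])
        cy0, cy1 = max(y0, 0), min(y1, self.shape[1])
        cz0, cz1 = max(z0, 0), min(z1, self.shape[2])
        if cx0 >= cx1 or cy0 >= cy1 or cz0 >= cz1:
            return out
        b = self.block_size
        for i in range(cx0 // b[0], (cx1 - 1) // b[0] + 1):
            for j in range(cy0 // b[1], (cy1 - 1) // b[1] + 1):
                for k in range(cz0 // b[2], (cz1 - 1) // b[2] + 1):
                    blk = read_block(self, (i, j, k))
                    (bx0, bx1), (by0, by1), (bz0, bz1) = self.block_extent((i, j, k))
                    sx0, sx1 = max(cx0, bx0), min(cx1, bx1)
                    sy0, sy1 = max(cy0, by0), min(cy1, by1)
                    sz0, sz1 = max(cz0, bz0), min(cz1, bz1)
                    out[sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0, sz0 - z0:sz1 - z0] = \
                        blk[sx0 - bx0:sx1 - bx0, sy0 - by0:sy1 - by0, sz0 - bz0:sz1 - bz0]
        return out


_META_NAME = "meta.json"


def create_block_store(shape, block_size, dtype, voxel_size=(1.0, 1.0, 1.0),
                       root=None, fill_value: float = 0.0) -> BlockStore:
    shape = tuple(int(s) for s in shape)
    if isinstance(block_size, int):
        block_size = (block_size,) * 3
    block_size = tuple(int(b) for b in block_size)
    if any(b < 8 for b in block_size):
        raise ValidationError(f"block_size components must be >= 8, got {block_size}")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    store = BlockStore(root, shape, block_size, np.dtype(dtype),
                       tuple(float(v) for v in voxel_size), float(fill_value))
    meta = {
        "shape": list(shape),
        "block_size": list(block_size),
        "dtype": np.dtype(dtype).name,
        "voxel_size": list(store.voxel_size),
        "fill_value": store.fill_value,
    }
    with open(root / _META_NAME, "w") as fh:
        json.dump(meta, fh, indent=1)
    return store


def open_block_store(root) -> BlockStore:
    root = Path(root)
    meta_path = root / _META_NAME
    if not meta_path.exists():
        raise IOError(f"not a block store (missing {_META_NAME}): {root}")
    meta = json.loads(meta_path.read_text())
    return BlockStore(
        root,
        tuple(meta["shape"]),
        tuple(meta["block_size"]),
        np.dtype(meta["dtype"]),
        tuple(meta["voxel_size"]),
        float(meta.get("fill_value", 0.0)),
    )


def read_block(store: BlockStore, idx) -> np.ndarray:
    store._check_idx(idx)
    p = store._block_path(idx)
    shp = store.block_shape(idx)
    if not p.exists():
        return np.full(shp, store.fill_value, dtype=store.dtype)
    arr = tifffile.imread(p).transpose(2, 1, 0)
    if arr.shape != shp:
        raise FormatError(f"block {tuple(idx)} on disk has shape {arr.shape}, expected {shp}")
    return arr.astype(store.dtype, copy=False)


def write_block(store: BlockStore, idx, data: np.ndarray) -> None:
    store._check_idx(idx)
    data = np.asarray(data)
    shp = store.block_shape(idx)
    if data.shape != shp:
        raise ValidationError(f"block {tuple(idx)} must have shape {shp}, got {data.shape}")
    tifffile.imwrite(store._block_path(idx),
                     np.ascontiguousarray(data.astype(store.dtype, copy=False).transpose(2, 1, 0)))


def ingest_volume(store: BlockStore, v: Volume3D) -> None:
    """Partition a whole volume into the store (inverse of assemble_volume)."""
    if v.shape != store.shape:
        raise ValidationError(f"volume shape {v.shape} != store shape {store.shape}")
    for idx in store.iter_indices():
        (x0, x1), (y0, y1), (z0, z1) = store.block_extent(idx)
        write_block(store, idx, v.data[x0:x1, y0:y1, z0:z1])


def assemble_volume(store: BlockStore) -> Volume3D:
    out = np.empty(store.shape, dtype=store.dtype)
    for idx in store.iter_indices():
        (x0, x1), (y0, y1), (z0, z1) = store.block_extent(idx)
        out[x0:x1, y0:y1, z0:z1] = read_block(store, idx)
    return Volume3D(out, store.voxel_size)
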