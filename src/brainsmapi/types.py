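"""Core domain containers shared by every stage of the pipeline.

Conventions
-----------
* Axis order is ``(x, y, z)`` everywhere in memory: ``data[ix, iy, iz]``.
  At I/O boundaries (TIFF slice stacks) the necessary transposes are applied
  so that x is the fastest-varying index on disk.
* Voxel coordinates are 0-based; extents are half-open; the physical
  coordinate of a voxel is ``index * voxel_size`` (micrometres).
* Affine transforms use the ROW-VECTOR convention: a point maps as
  ``[x, y, z, 1] @ matrix``.
* Displacement fields are PULL-BACK fields in voxel units: for an output
  (fixed-space) coordinate ``q``, the source coordinate that is sampled is
  ``affine(q) + field(q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "LabelVolume",
    "AffineTransform",
    "DisplacementField",
    "SWCNeuron",
    "ValidationError",
    "FormatError",
    "ConvergenceError",
]


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValueError):
    """An on-disk artifact does not follow its documented dialect."""


class ConvergenceError(RuntimeError):
    """An iterative optimizer failed to converge; carries its trace."""

    def __init__(self, message: str, trace: Sequence[float] | None = None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


@dataclass
class Volume3D:
    """A 3D scalar grid with per-axis physical voxel size in micrometres."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"Volume3D data must be 3D, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size must be 3 positive numbers, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer-coded anatomical regional features plus a label-name table.

    Label 0 is background by convention; every nonzero label that occurs in
    ``labels`` must have an entry in ``names``.
    """

    labels: np.ndarray
    names: dict[int, str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("LabelVolume labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("LabelVolume labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative (0 = background)")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"labels present but unnamed: {sorted(missing)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class AffineTransform:
    """Homogeneous affine under the row-vector convention.

    A point maps as ``[x, y, z, 1] @ matrix``; consequently the LAST COLUMN
    must be ``(0, 0, 0, 1)^T`` and the translation lives in the last row.
    2D variants (3x3 matrices) are accepted for the planar model experiment.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] not in (3, 4):
            raise ValidationError(f"affine matrix must be 3x3 or 4x4, got {m.shape}")
        d = m.shape[0] - 1
        expected = np.zeros(d + 1)
        expected[-1] = 1.0
        if not np.allclose(m[:, -1], expected, atol=1e-9):
            raise ValidationError("last column must be (0,...,0,1)^T under the row-vector convention")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValidationError("affine matrix is not invertible")
        self.matrix = m

    @property
    def ndim(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def linear(self) -> np.ndarray:
        """The d x d linear block (applied as ``v @ linear``)."""
        d = self.ndim
        return self.matrix[:d, :d]

    @property
    def translation(self) -> np.ndarray:
        d = self.ndim
        return self.matrix[d, :d]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, d) array of points: ``p -> [p, 1] @ matrix``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear + self.translation

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls, ndim: int = 3) -> "AffineTransform":
        return cls(np.eye(ndim + 1))


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors on the working-resolution lattice.

    Stored as an array of shape ``(d, *spatial)`` where ``components[i]`` is
    the displacement along axis ``i`` in working-resolution VOXEL units.
    Semantics are pull-back: ``source(q) = affine(q) + field(q)``.
    """

    components: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.components)
        if c.ndim not in (3, 4) or c.shape[0] != c.ndim - 1:
            raise ValidationError(
                f"field must have shape (d, *spatial) with d == ndim, got {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValidationError("displacement field must be finite everywhere")
        self.components = c

    @property
    def ndim(self) -> int:
        return self.components.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        """Spatial lattice shape."""
        return self.components.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.components.astype(np.float64) ** 2, axis=0))

    @classmethod
    def zeros(cls, shape: Sequence[int]) -> "DisplacementField":
        shape = tuple(shape)
        return cls(np.zeros((len(shape),) + shape, dtype=np.float32))


_SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass
class SWCNeuron:
    """A traced neuron as parent-linked sequence points (SWC node table)."""

    nodes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_SWC_COLUMNS))

    def __post_init__(self):
        df = pd.DataFrame(self.nodes, columns=_SWC_COLUMNS).copy()
        for c in ("id", "type", "parent"):
            df[c] = df[c].astype(int)
        for c in ("x", "y", "z", "radius"):
            df[c] = df[c].astype(float)
        ids = df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise FormatError("SWC node ids must be unique")
        known = set(ids.tolist())
        for p in df["parent"]:
            if p != -1 and p not in known:
                raise FormatError(f"SWC node references absent parent id {p}")
        self.nodes = df.reset_index(drop=True)

    @property
    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, coords: np.ndarray, radii: np.ndarray | None = None) -> "SWCNeuron":
        df = self.nodes.copy()
        df[["x", "y", "z"]] = np.asarray(coords, dtype=float)
        if radii is not None:
            df["radius"] = np.asarray(radii, dtype=float)
        return SWCNeuron(df)

    def topology_key(self) -> tuple:
        """Hashable (ids, types, parents) triple; invariant under any spatial map."""
        return (
            tuple(self.nodes["id"]),
            tuple(self.nodes["type"]),
            tuple(self.nodes["parent"]),
        )

    def segments(self) -> np.ndarray:
        """(M, 2, 3) array of parent->child coordinate pairs (roots excluded)."""
        df = self.nodes
        by_id = {int(i): j for j, i in enumerate(df["id"])}
        pairs = []
        xyz = self.coords
        for j, p in enumerate(df["parent"]):
            if p != -1:
                pairs.append((xyz[by_id[int(p)]], xyz[j]))
        return np.asarray(pairs, dtype=float).reshape(-1, 2, 3)
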