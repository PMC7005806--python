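"""Volume preparation: illumination correction, isotropic resampling, outline extraction.

The illumination model is multiplicative (staining / light-field gain), so
correction divides each z-slice by a heavily smoothed background estimate
and rescales to preserve the slice mean.  The outline extractor mirrors the
usual microscopy recipe: per-slice adaptive (local-mean) threshold, 3D hole
filling, morphological opening and closing, largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.morphology import ball

from .types import LabelVolume, ValidationError, Volume3D

__all__ = ["PreprocessConfig", "correct_illumination", "resample_isotropic", "extract_outline"]


@dataclass
class PreprocessConfig:
    background_sigma: float = 25.0   # px, low-pass scale of the background estimate
    target_voxel: float = 10.0       # um, isotropic resampling target
    threshold_block: int = 51        # px, adaptive-threshold neighbourhood (odd)
    morph_radius: int = 2            # px, ball radius for opening/closing

    def __post_init__(self):
        if min(self.background_sigma, self.target_voxel, self.threshold_block,
               self.morph_radius) <= 0:
            raise ValidationError("all preprocessing parameters must be positive")


def correct_illumination(v: Volume3D, cfg: PreprocessConfig | None = None) -> Volume3D:
    """Divide each z-slice by its smoothed background, preserving the slice mean."""
    cfg = cfg or PreprocessConfig()
    data = np.asarray(v.data)
    if data.min() < 0:
        raise ValidationError("illumination correction expects a non-negative volume")
    out = np.empty_like(data, dtype=np.float64)
    for k in range(data.shape[2]):
        sl = data[:, :, k].astype(np.float64)
        mean = sl.mean()
        if mean == 0.0:
            out[:, :, k] = sl  # all-zero slice passes through unchanged
            continue
        bg = ndimage.gaussian_filter(sl, cfg.background_sigma, mode="nearest")
        bg = np.maximum(bg, 1e-12)
        corrected = sl / bg
        out[:, :, k] = corrected * (mean / corrected.mean())
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(data.dtype)
    else:
        out = out.astype(data.dtype)
    return Volume3D(out, v.voxel_size)


def resample_isotropic(v: Volume3D, target: float) -> Volume3D:
    """Trilinear resampling onto an isotropic grid of ``target`` um voxels.

    The new shape is ``round(old_shape * voxel_size / target)`` per axis;
    a target equal to an already-isotropic voxel size is the identity.
    """
    if target <= 0:
        raise ValidationError("target voxel size must be > 0")
    if all(abs(s - target) < 1e-12 for s in v.voxel_size):
        return Volume3D(v.data.copy(), (target,) * 3)
    new_shape = tuple(
        int(round(s * vs / target)) for s, vs in zip(v.shape, v.voxel_size)
    )
    if min(new_shape) < 1:
        raise ValidationError(f"target {target} um collapses the volume to {new_shape}")
    zoom = [n / s for n, s in zip(new_shape, v.shape)]
    data = ndimage.zoom(v.data.astype(np.float64), zoom, order=1, mode="nearest",
                        grid_mode=True)
    if np.issubdtype(v.data.dtype, np.integer):
        info = np.iinfo(v.data.dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(v.data.dtype)
    else:
        data = data.astype(v.data.dtype)
    return Volume3D(data, (target,) * 3)


def extract_outline(v: Volume3D, cfg: PreprocessConfig | None = None) -> LabelVolume:
    """Binary brain-outline mask: threshold, fill, open/close, largest component."""
    cfg = cfg or PreprocessConfig()
    data = np.asarray(v.data).astype(np.float64)
    block = int(cfg.threshold_block) | 1  # threshold_local requires an odd block
    mask = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[2]):
        sl = data[:, :, k]
        if sl.max() == sl.min():
            continue
        mask[:, :, k] = sl > threshold_local(sl, block_size=block, method="mean", offset=0.0)
    if not mask.any():
        warnings.warn("no foreground found; returning an empty outline mask", RuntimeWarning)
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), {}, v.voxel_size)
    mask = ndimage.binary_fill_holes(mask)
    selem = ball(int(cfg.morph_radius))
    mask = ndimage.binary_opening(mask, structure=selem)
    mask = ndimage.binary_closing(mask, structure=selem)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n == 0:
        warnings.warn("morphology removed all foreground; returning an empty outline mask",
                      RuntimeWarning)
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), {}, v.voxel_size)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    out = (lab == keep).astype(np.int32)
    return LabelVolume(out, {1: "Outline"}, v.voxel_size)
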