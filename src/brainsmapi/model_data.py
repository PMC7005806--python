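"""Synthetic validation data: 2D cartoon face models and 3D brain fixtures.

The face-model chain emulates the classic registration torture test: a
smiling fixed model, a "crying" deformed copy (Model 1), random per-region
gray textures simulating weak SNR (Model 2), sinusoidal streak noise
simulating uneven illumination (Model 3) and a triangular zeroed tear
simulating sample damage (Model 4).  The 3D generators produce label/gray
volume pairs related by a known smooth invertible deformation so that the
whole pipeline is testable at desk scale.

Every generator is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import fields
from .types import DisplacementField, LabelVolume, ValidationError, Volume3D

__all__ = [
    "FaceModel",
    "SyntheticDeformation",
    "make_fixed_model",
    "crying_deformation",
    "make_model1",
    "surrogate_histograms",
    "texture_from_histograms",
    "add_streak_noise",
    "add_tear",
    "make_model2",
    "make_model3",
    "make_model4",
    "make_synthetic_brain",
    "make_synthetic_field",
]

FACE_SIZE = 400

DEFAULT_FACE_PARAMS = {
    "size": FACE_SIZE,
    "center": (200.0, 200.0),
    "face_radius": 150.0,
    "face_gray": 100,
    "eye_centers": ((135.0, 150.0), (265.0, 150.0)),
    "eye_radius": 16.0,
    "eye_gray": 170,
    "brow_inner": 24.0,
    "brow_outer": 34.0,
    "brow_gray": 220,
    "mouth_center": (200.0, 160.0),
    "mouth_inner": 85.0,
    "mouth_outer": 100.0,
    "mouth_min_y": 225.0,
    "mouth_gray": 255,
}


@dataclass
class FaceModel:
    """A 2D cartoon model: image indexed ``image[x, y]`` plus named masks."""

    image: np.ndarray
    region_masks: dict[str, np.ndarray]
    params: dict = dc_field(default_factory=dict)
    tear_mask: np.ndarray | None = None

    def __post_init__(self):
        names = list(self.region_masks)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if np.any(self.region_masks[names[a]] & self.region_masks[names[b]]):
                    raise ValidationError(
                        f"region masks {names[a]!r} and {names[b]!r} overlap"
                    )

    def label_image(self, order=("face", "eyebrows", "eyes", "mouth")) -> np.ndarray:
        """Integer label image: 0 background, then 1.. in the given order."""
        out = np.zeros(self.image.shape, dtype=np.int32)
        for i, name in enumerate(order, start=1):
            out[self.region_masks[name]] = i
        return out


@dataclass
class SyntheticDeformation:
    """A known smooth deformation with a numerically verified positive Jacobian."""

    field: DisplacementField
    amplitude: float
    smoothness: float
    seed: int

    def __post_init__(self):
        det = fields.jacobian_determinant(np.asarray(self.field.components))
        self.min_jacobian = float(det.min())
        if self.min_jacobian <= 0:
            raise ValidationError(
                f"deformation is not invertible: min Jacobian det = {self.min_jacobian:.4f}"
            )


def _grid2(size):
    x, y = np.indices((size, size), dtype=float)
    return x, y


def make_fixed_model(params: dict | None = None) -> FaceModel:
    """The round smiling face with distinct gray values per feature."""
    p = dict(DEFAULT_FACE_PARAMS)
    if params:
        p.update(params)
    size = int(p["size"])
    x, y = _grid2(size)
    cx, cy = p["center"]
    face = (x - cx) ** 2 + (y - cy) ** 2 <= p["face_radius"] ** 2

    eyes = np.zeros_like(face)
    brows = np.zeros_like(face)
    for ex, ey in p["eye_centers"]:
        r2 = (x - ex) ** 2 + (y - ey) ** 2
        eyes |= r2 <= p["eye_radius"] ** 2
        ring = (r2 >= p["brow_inner"] ** 2) & (r2 <= p["brow_outer"] ** 2)
        brows |= ring & (y < ey - 12.0)

    mx, my = p["mouth_center"]
    mr2 = (x - mx) ** 2 + (y - my) ** 2
    mouth = (mr2 >= p["mouth_inner"] ** 2) & (mr2 <= p["mouth_outer"] ** 2) & (y >= p["mouth_min_y"])

    img = np.zeros((size, size), dtype=np.uint8)
    img[face] = p["face_gray"]
    img[brows] = p["brow_gray"]
    img[eyes] = p["eye_gray"]
    img[mouth] = p["mouth_gray"]
    masks = {
        "face": face & ~(brows | eyes | mouth),
        "eyebrows": brows,
        "eyes": eyes,
        "mouth": mouth,
    }
    return FaceModel(img, masks, p)


def crying_deformation(size: int = FACE_SIZE, amplitude: float = 4.0,
                       smoothness: float = 30.0, seed: int = 0,
                       mouth_amplitude: float = 9.0) -> SyntheticDeformation:
    """The deterministic deformation turning the smile into a cry.

    A localized vertical warp centred on the mouth (flipping the arc's
    apparent curvature) is added to a smooth random field over the whole
    frame; invertibility is verified numerically.
    """
    base = make_synthetic_field((size, size), amplitude, smoothness, seed)
    f = np.asarray(base.field.components).copy()
    x, y = _grid2(size)
    p = DEFAULT_FACE_PARAMS
    mx = p["mouth_center"][0]
    my = 240.0  # vertical centre of the smile arc
    bump = np.exp(-(((x - mx) / 80.0) ** 2 + ((y - my) / 35.0) ** 2) / 2.0)
    f[1] += mouth_amplitude * bump * np.cos(np.pi * (x - mx) / 180.0)
    return SyntheticDeformation(DisplacementField(f), amplitude, smoothness, seed)


def make_model1(fixed: FaceModel, deform: SyntheticDeformation) -> FaceModel:
    """Warp the fixed model (and all its masks) by a known deformation."""
    f = np.asarray(deform.field.components)
    if f.shape[1:] != fixed.image.shape:
        raise ValidationError("deformation lattice does not match the model")
    img = fields.warp_image(fixed.image.astype(np.float32), f, order=1)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    masks = {
        name: fields.warp_image(m.astype(np.uint8), f, order=0).astype(bool)
        for name, m in fixed.region_masks.items()
    }
    return FaceModel(img, masks, dict(fixed.params))


def surrogate_histograms(seed: int = 0) -> dict[str, np.ndarray]:
    """Three overlapping discretized Gaussian gray histograms.

    Stand-ins for empirical Nissl histograms of white matter, hippocampus
    and cerebellum; the overlap is what makes the textures a weak-SNR test.
    """
    out = {}
    for name, (mu, sig) in {
        "eyebrows": (90.0, 18.0),
        "eyes": (150.0, 18.0),
        "mouth": (210.0, 18.0),
    }.items():
        v = np.arange(256, dtype=float)
        h = np.exp(-0.5 * ((v - mu) / sig) ** 2)
        out[name] = h / h.sum()
    return out


def texture_from_histograms(m: FaceModel, histograms: dict[str, np.ndarray],
                            seed: int = 0) -> FaceModel:
    """Replace each listed region's pixels by i.i.d. draws from its histogram."""
    rng = np.random.default_rng(seed)
    img = m.image.copy()
    for name, hist in histograms.items():
        hist = np.asarray(hist, dtype=float)
        if hist.shape != (256,) or np.any(hist < 0) or hist.sum() <= 0:
            raise ValidationError(f"histogram for {name!r} is not a distribution over 0-255")
        hist = hist / hist.sum()
        mask = m.region_masks[name]
        img[mask] = rng.choice(256, size=int(mask.sum()), p=hist).astype(np.uint8)
    return FaceModel(img, {k: v.copy() for k, v in m.region_masks.items()},
                     dict(m.params), m.tear_mask)


def add_streak_noise(image: np.ndarray, w: float = 20.0, A: float = 7.0,
                     axis: int = 1, literal: bool = False) -> np.ndarray:
    """Multiplicative sinusoidal streak noise: ``y = v * (sin((pi/w) c) + A - 1) / A``.

    ``v`` is the pixel value and ``c`` the spatial coordinate along ``axis``
    (period ``2w`` pixels), producing stripes perpendicular to that axis.
    With ``literal=True`` the verbatim value-dependent reading ``c = v`` is
    applied instead (banding by gray level rather than by position).
    """
    if w <= 0:
        raise ValidationError("streak period w must be > 0")
    if A <= 1:
        raise ValidationError("attenuation A must be > 1 (A <= 1 can flip signs)")
    img = np.asarray(image)
    v = img.astype(np.float64)
    if literal:
        c = v
    else:
        shape = [1] * img.ndim
        shape[axis] = img.shape[axis]
        c = np.arange(img.shape[axis], dtype=float).reshape(shape)
    out = v * (np.sin((np.pi / w) * c) + A - 1.0) / A
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out.astype(img.dtype)


def _triangle_mask(shape, triangle) -> np.ndarray:
    """Pixels whose centers fall inside (or exactly on the edges of) the triangle."""
    (x1, y1), (x2, y2), (x3, y3) = [(float(a), float(b)) for a, b in triangle]
    area2 = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    if abs(area2) < 1e-9:
        raise ValidationError("degenerate triangle")
    x, y = np.indices(shape, dtype=float)
    s1 = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
    s2 = (x3 - x2) * (y - y2) - (y3 - y2) * (x - x2)
    s3 = (x1 - x3) * (y - y3) - (y1 - y3) * (x - x3)
    if area2 < 0:
        s1, s2, s3 = -s1, -s2, -s3
    return (s1 >= 0) & (s2 >= 0) & (s3 >= 0)


def add_tear(m: FaceModel, triangle) -> FaceModel:
    """Zero a triangular area to simulate a torn sample; the tear mask is recorded."""
    tear = _triangle_mask(m.image.shape, triangle)
    img = m.image.copy()
    img[tear] = 0
    return FaceModel(img, {k: v.copy() for k, v in m.region_masks.items()},
                     dict(m.params), tear)


DEFAULT_TEAR_TRIANGLE = ((168.0, 228.0), (232.0, 236.0), (200.0, 262.0))


def make_model2(model1: FaceModel, histograms=None, seed: int = 2) -> FaceModel:
    return texture_from_histograms(model1, histograms or surrogate_histograms(), seed)


def make_model3(model2: FaceModel, w: float = 20.0, A: float = 7.0, axis: int = 1) -> FaceModel:
    img = add_streak_noise(model2.image, w=w, A=A, axis=axis)
    return FaceModel(img, {k: v.copy() for k, v in model2.region_masks.items()},
                     dict(model2.params), model2.tear_mask)


def make_model4(model3: FaceModel, triangle=DEFAULT_TEAR_TRIANGLE) -> FaceModel:
    return add_tear(model3, triangle)


# ---------------------------------------------------------------------------
# 3D fixtures

def make_synthetic_brain(shape=(64, 64, 64), n_regions: int = 5,
                         seed: int = 0) -> tuple[Volume3D, LabelVolume]:
    """A smooth ellipsoidal outline containing nested blob regions.

    Label 1 is the outline (tissue between blobs); labels 2..n_regions are
    ellipsoidal blobs placed inside it.  The gray channel gives each label a
    distinct mean intensity plus Gaussian texture noise.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValidationError("shape must be at least 32 per axis")
    if n_regions < 3:
        raise ValidationError("need n_regions >= 3")
    rng = np.random.default_rng(seed)
    idx = np.indices(shape, dtype=float)
    center = np.asarray([(s - 1) / 2.0 for s in shape])
    semi = np.asarray([0.42 * s for s in shape])
    r2 = sum(((idx[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    outline = r2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    labels[outline] = 1
    min_dim = min(shape)
    for lab in range(2, n_regions + 1):
        for _attempt in range(100):
            c = center + (rng.uniform(-0.55, 0.55, size=3)) * semi
            rad = rng.uniform(max(3.0, 0.07 * min_dim), 0.15 * min_dim, size=3)
            b2 = sum(((idx[d] - c[d]) / rad[d]) ** 2 for d in range(3))
            blob = (b2 <= 1.0) & (labels == 1)
            if blob.sum() >= 30:
                labels[blob] = lab
                break
        else:
            raise RuntimeError(f"could not place region {lab}")

    means = np.concatenate([[8.0], np.linspace(60.0, 230.0, n_regions)])
    gray = means[labels] + rng.normal(0.0, 8.0, size=shape)
    gray = ndimage.gaussian_filter(gray, 0.6)
    vol = Volume3D(np.clip(np.rint(gray), 0, 255).astype(np.uint8))
    names = {1: "outline"}
    names.update({lab: f"region_{lab}" for lab in range(2, n_regions + 1)})
    return vol, LabelVolume(labels, names)


def make_synthetic_field(shape, amplitude: float, smoothness: float,
                         seed: int = 0, max_tries: int = 5) -> SyntheticDeformation:
    """Gaussian-smoothed white-noise field rescaled to a given max norm.

    ``amplitude <= smoothness`` is required as the invertibility heuristic;
    the Jacobian of ``id + field`` is then verified numerically, retrying
    with a derived seed on the rare failure.
    """
    shape = tuple(int(s) for s in shape)
    if amplitude < 0 or smoothness <= 0:
        raise ValidationError("amplitude must be >= 0 and smoothness > 0")
    if amplitude > smoothness:
        raise ValidationError(
            f"amplitude ({amplitude}) must not exceed smoothness ({smoothness})"
        )
    d = len(shape)
    if amplitude == 0:
        zero = DisplacementField(np.zeros((d,) + shape, dtype=np.float32))
        return SyntheticDeformation(zero, 0.0, smoothness, seed)
    last_err = None
    for t in range(max_tries):
        rng = np.random.default_rng(seed + 100003 * t)
        # wrap gives stationary statistics; edge-replicating modes inflate the
        # boundary variance and make the max-normalized field vanish inside
        f = np.stack([
            ndimage.gaussian_filter(rng.standard_normal(shape), smoothness, mode="wrap")
            for _ in range(d)
        ])
        norm = np.sqrt((f ** 2).sum(axis=0)).max()
        f = (f / norm * amplitude).astype(np.float64)
        try:
            return SyntheticDeformation(DisplacementField(f), amplitude, smoothness, seed)
        except ValidationError as e:  # Jacobian check failed; retry
            last_err = e
    raise last_err
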