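"""Shared registration harnesses.

The two expensive fixtures (the 2D model-face registration and the 3D
known-field recovery) are computed once per session and shared between the
unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import brainsmapi as bm
from brainsmapi import fields
from brainsmapi.types import LabelVolume

FACE_REGION_ORDER = ("face", "eyebrows", "eyes", "mouth")


@pytest.fixture(scope="session")
def face_harness():
    """Fixed model, Models 1-4 and the registration of their shared features."""
    fixed = bm.make_fixed_model()
    deform = bm.crying_deformation(seed=0)
    m1 = bm.make_model1(fixed, deform)
    m2 = bm.make_model2(m1, seed=1)
    m3 = bm.make_model3(m2)
    m4 = bm.make_model4(m3)

    fixed_labels = fixed.label_image(FACE_REGION_ORDER)
    moving_labels = m1.label_image(FACE_REGION_ORDER)
    cfg = bm.RegistrationConfig(levels=(4, 2, 1), iters_per_level=(100, 80, 50), seed=0)
    f = bm.encode_features(fixed_labels, [1, 2, 3, 4])
    m = bm.encode_features(moving_labels, [1, 2, 3, 4])
    M = bm.register_affine(f, m, cfg)
    result = bm.register_diffeomorphic(f, m, init=M, cfg=cfg)
    warped_labels = bm.apply_transform_lowres(moving_labels, result.M, result.phi2)
    return {
        "fixed": fixed,
        "deform": deform,
        "models": {1: m1, 2: m2, 3: m3, 4: m4},
        "fixed_labels": fixed_labels,
        "moving_labels": moving_labels,
        "result": result,
        "warped_labels": warped_labels,
    }


@pytest.fixture(scope="session")
def brain_recovery():
    """64^3 known-field recovery: labels warped by a known deformation, re-registered."""
    import time
    t0 = time.time()
    vol, labs = bm.make_synthetic_brain(shape=(64, 64, 64), n_regions=5, seed=11)
    truth = np.asarray(
        bm.make_synthetic_field((64, 64, 64), amplitude=3.0, smoothness=8.0,
                                seed=21).field.components)
    moving = fields.warp_image(labs.labels.astype(np.float64), truth,
                               order=0).astype(np.int32)
    moving_lv = LabelVolume(moving, dict(labs.names))
    regions = [1, 2, 3, 4, 5]
    cfg = bm.RegistrationConfig(levels=(4, 2, 1), iters_per_level=(100, 80, 50), seed=0)
    f = bm.encode_features(labs, regions)
    m = bm.encode_features(moving_lv, regions)
    M = bm.register_affine(f, m, cfg)
    result = bm.register_diffeomorphic(f, m, init=M, cfg=cfg)
    warped = bm.apply_transform_lowres(moving_lv, result.M, result.phi2)
    return {
        "wall_time_s": time.time() - t0,
        "volume": vol,
        "labels": labs,
        "truth_field": truth,
        "moving": moving_lv,
        "regions": regions,
        "result": result,
        "warped": warped,
    }


def forward_epe(result, truth_field, mask, stride=7):
    """Endpoint error of the recovered forward map vs the generating field.

    The moving volume was built as ``moving(x) = fixed(x + w(x))``, so the
    true forward (moving -> fixed) map is ``T(p) = p + w(p)``.  The recovered
    map is ``p -> q + phi1(q)`` with ``q = [p] @ M^-1``.  Evaluated on every
    ``stride``-th voxel of ``mask``.
    """
    from brainsmapi.volume_transform import interp_field

    pts = np.argwhere(mask).astype(float)[::stride]
    q = result.M.inverse().apply(pts)
    est = q + interp_field(result.phi1, q)
    w = np.stack([truth_field[i][mask] for i in range(truth_field.shape[0])]).T[::stride]
    true = pts + w
    return np.linalg.norm(est - true, axis=1)


def inverse_consistency_norm(result):
    """Per-voxel norm of phi1 composed with phi2 (in the prealigned frame)."""
    u2 = np.asarray(result.phi2.components, dtype=np.float64)
    A = result.M.linear
    u = np.einsum("i...,ij->j...", u2, np.linalg.inv(A))
    c = fields.compose(np.asarray(result.phi1.components, np.float64), u)
    return np.sqrt((c ** 2).sum(axis=0))
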