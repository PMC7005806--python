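import numpy as np
import pytest

import brainsmapi as bm
from brainsmapi.model_data import DEFAULT_TEAR_TRIANGLE, _triangle_mask
from brainsmapi.types import ValidationError


def test_fixed_model_shape_and_determinism():
    a = bm.make_fixed_model()
    b = bm.make_fixed_model()
    assert a.image.shape == (400, 400) and a.image.dtype == np.uint8
    assert np.array_equal(a.image, b.image)
    for name, m in a.region_masks.items():
        assert m.dtype == bool and m.any(), name


def test_fixed_model_masks_disjoint():
    m = bm.make_fixed_model()
    names = list(m.region_masks)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            assert not (m.region_masks[names[i]] & m.region_masks[names[j]]).any()
    assert int((m.region_masks["eyes"] & m.region_masks["mouth"]).sum()) == 0


def test_model1_zero_deformation_is_identity():
    fixed = bm.make_fixed_model()
    zero = bm.make_synthetic_field((400, 400), 0.0, 30.0, seed=0)
    m1 = bm.make_model1(fixed, zero)
    assert np.array_equal(m1.image, fixed.image)
    for name in fixed.region_masks:
        assert np.array_equal(m1.region_masks[name], fixed.region_masks[name])


def test_model1_mouth_centroid_moves_with_field():
    fixed = bm.make_fixed_model()
    deform = bm.crying_deformation(seed=0)
    m1 = bm.make_model1(fixed, deform)
    mask = fixed.region_masks["mouth"]
    c_fixed = np.argwhere(mask).mean(axis=0)
    c_moved = np.argwhere(m1.region_masks["mouth"]).mean(axis=0)
    # pull-back warp: to first order each mask point y lands at y - f(y),
    # so the centroid moves by minus the mean field over the mask
    f = np.asarray(deform.field.components)
    expect = c_fixed - np.array([f[0][mask].mean(), f[1][mask].mean()])
    assert np.linalg.norm(c_moved - expect) < 2.0


def test_model_chain_preserves_masks():
    fixed = bm.make_fixed_model()
    m1 = bm.make_model1(fixed, bm.crying_deformation(seed=0))
    m2 = bm.make_model2(m1, seed=1)
    m3 = bm.make_model3(m2)
    m4 = bm.make_model4(m3)
    for name in m1.region_masks:
        assert np.array_equal(m1.region_masks[name], m4.region_masks[name])
    assert m4.tear_mask is not None and m4.tear_mask.any()
    assert np.all(m4.image[m4.tear_mask] == 0)


def test_texture_histogram_examples():
    fixed = bm.make_fixed_model()
    # degenerate histogram {v: 1.0} -> region constant v
    h = np.zeros(256)
    h[37] = 1.0
    out = bm.texture_from_histograms(fixed, {"eyes": h}, seed=0)
    assert np.all(out.image[fixed.region_masks["eyes"]] == 37)
    assert np.array_equal(out.image[~fixed.region_masks["eyes"]],
                          fixed.image[~fixed.region_masks["eyes"]])
    # same seed -> identical
    a = bm.make_model2(fixed, seed=5)
    b = bm.make_model2(fixed, seed=5)
    assert np.array_equal(a.image, b.image)
    with pytest.raises(ValidationError):
        bm.texture_from_histograms(fixed, {"eyes": np.zeros(256)}, seed=0)


def test_texture_histogram_law_of_large_numbers():
    fixed = bm.make_fixed_model()
    hists = bm.surrogate_histograms()
    out = bm.texture_from_histograms(fixed, {"face": hists["eyes"]}, seed=3)
    vals = out.image[fixed.region_masks["face"]]
    assert vals.size >= 10_000
    emp = np.bincount(vals, minlength=256) / vals.size
    tv = 0.5 * np.abs(emp - hists["eyes"]).sum()
    assert tv < 0.05


def test_streak_noise_examples():
    img = np.zeros((40, 40), dtype=np.uint8)
    assert np.all(bm.add_streak_noise(img) == 0)  # zero multiplier
    # sin = 1 at c = w/2 -> unchanged value
    img = np.full((40, 40), 200.0)
    out = bm.add_streak_noise(img, w=20.0, A=7.0, axis=0)
    assert abs(out[10, 0] - 200.0) < 1e-9
    # sin = 0, v = 140, A = 7 -> 120 (value-dependent literal reading)
    lit = bm.add_streak_noise(np.full((4, 4), 140.0), w=20.0, A=7.0, literal=True)
    assert np.allclose(lit, 120.0)
    # spatial reading: c = 0 row has sin = 0 -> 140 * 6/7 = 120
    sp = bm.add_streak_noise(np.full((4, 4), 140.0), w=20.0, A=7.0, axis=0)
    assert abs(sp[0, 0] - 120.0) < 1e-9
    with pytest.raises(ValidationError):
        bm.add_streak_noise(img, w=0.0)
    with pytest.raises(ValidationError):
        bm.add_streak_noise(img, A=1.0)


def test_streak_noise_clips_to_dtype():
    img = np.full((4, 4), 250, dtype=np.uint8)
    out = bm.add_streak_noise(img, w=20.0, A=2.0, axis=0)
    assert out.dtype == np.uint8 and out.max() <= 255


def test_tear_triangle_rasterization():
    # right triangle (0,0),(10,0),(0,10), centre-of-pixel inclusive rule
    mask = _triangle_mask((20, 20), ((0, 0), (10, 0), (0, 10)))
    n = int(mask.sum())
    assert 55 <= n <= 66
    # recount by an independent point-in-triangle test
    cnt = 0
    for x in range(20):
        for y in range(20):
            if x >= 0 and y >= 0 and x + y <= 10:
                cnt += 1
    assert n == cnt
    with pytest.raises(ValidationError):
        _triangle_mask((20, 20), ((0, 0), (5, 5), (10, 10)))


def test_tear_outside_image_is_noop():
    fixed = bm.make_fixed_model()
    out = bm.add_tear(fixed, ((500, 500), (510, 500), (500, 510)))
    assert np.array_equal(out.image, fixed.image)
    assert not out.tear_mask.any()


def test_tear_mask_recount():
    fixed = bm.make_fixed_model()
    out = bm.add_tear(fixed, DEFAULT_TEAR_TRIANGLE)
    recount = _triangle_mask(fixed.image.shape, DEFAULT_TEAR_TRIANGLE)
    assert np.array_equal(out.tear_mask, recount)
    assert np.all(out.image[recount] == 0)


def test_synthetic_brain_contract():
    v1, l1 = bm.make_synthetic_brain(shape=(48, 48, 48), n_regions=4, seed=9)
    v2, l2 = bm.make_synthetic_brain(shape=(48, 48, 48), n_regions=4, seed=9)
    assert np.array_equal(v1.data, v2.data) and np.array_equal(l1.labels, l2.labels)
    assert (l1.labels == 0).mean() > 0.3
    assert set(np.unique(l1.labels)) == {0, 1, 2, 3, 4}
    with pytest.raises(ValidationError):
        bm.make_synthetic_brain(shape=(16, 48, 48))
    with pytest.raises(ValidationError):
        bm.make_synthetic_brain(n_regions=2)


def test_synthetic_field_contract():
    zero = bm.make_synthetic_field((32, 32, 32), 0.0, 8.0, seed=0)
    assert np.all(np.asarray(zero.field.components) == 0)
    f = bm.make_synthetic_field((64, 64, 64), 2.0, 8.0, seed=1)
    norm = np.sqrt((np.asarray(f.field.components) ** 2).sum(axis=0))
    assert abs(norm.max() - 2.0) < 1e-6
    assert f.min_jacobian > 0
    with pytest.raises(ValidationError):
        bm.make_synthetic_field((32, 32, 32), 10.0, 8.0)  # amplitude > smoothness


def test_synthetic_field_invertible_in_practice():
    from brainsmapi.types import DisplacementField
    f = bm.make_synthetic_field((32, 32, 32), 2.0, 8.0, seed=2)
    inv = bm.invert_field(DisplacementField(np.asarray(f.field.components)))
    assert inv.residual < 0.1
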