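import numpy as np
import pytest

import brainsmapi as bm
from brainsmapi.types import LabelVolume, ValidationError


# ---------------------------------------------------------------------------
# Dice

def test_dice_unit_cases():
    a = np.zeros((4, 4), bool)
    a[:2] = True
    assert bm.dice(a, a) == 1.0
    assert bm.dice(a, ~a) == 0.0
    # |I| = 4, |J| = 6, |I n J| = 3 -> 0.6
    i = np.zeros(10, bool)
    j = np.zeros(10, bool)
    i[:4] = True
    j[1:7] = True
    assert bm.dice(i, j) == pytest.approx(0.6)


def test_dice_empty_and_errors():
    z = np.zeros((3, 3), bool)
    with pytest.warns(RuntimeWarning):
        assert bm.dice(z, z) == 1.0
    with pytest.raises(ValidationError):
        bm.dice(z, np.zeros((4, 4), bool))


def test_dice_symmetry():
    rng = np.random.default_rng(0)
    a = rng.random((16, 16)) < 0.3
    b = rng.random((16, 16)) < 0.3
    assert bm.dice(a, b) == bm.dice(b, a)


def _sphere_labels(shift=0):
    g = np.mgrid[0:40, 0:40, 0:40].astype(float)
    c = np.array([20.0 + shift, 20.0, 20.0])
    r = np.sqrt(((g - c[:, None, None, None]) ** 2).sum(axis=0))
    labs = (r < 10).astype(np.int32)
    return LabelVolume(labs, {1: "Sphere"})


def test_region_dice_report_identical_and_shifted():
    ref = _sphere_labels()
    reports = bm.region_dice_report(ref, ref, ["Sphere"], n_slices=10)
    assert len(reports) == 1
    r = reports[0]
    assert r.region == "Sphere" and r.median == 1.0 and all(s == 1.0 for s in r.scores)
    # slice indices stay within the region span along the chosen axis
    proj = np.flatnonzero((ref.labels == 1).any(axis=(0, 1)))
    assert min(r.slice_indices) >= proj[0] and max(r.slice_indices) <= proj[-1]
    shifted = _sphere_labels(shift=3)
    worse = bm.region_dice_report(shifted, ref, [1], n_slices=10)[0]
    assert 0.0 < worse.median < 1.0
    q1, q3 = worse.quartiles
    assert q1 <= worse.median <= q3


def test_region_dice_report_per_slice_oracle_recount():
    ref = _sphere_labels()
    moved = _sphere_labels(shift=2)
    rep = bm.region_dice_report(moved, ref, ["Sphere"], n_slices=7)[0]
    for k, s in zip(rep.slice_indices, rep.scores):
        a = moved.labels[:, :, k] == 1
        b = ref.labels[:, :, k] == 1
        inter = (a & b).sum()
        expect = 1.0 if (a.sum() + b.sum()) == 0 else 2 * inter / (a.sum() + b.sum())
        assert s == pytest.approx(expect)


def test_region_dice_report_thin_region_uses_all_slices():
    labs = np.zeros((20, 20, 20), np.int32)
    labs[5:8, 5:8, 9:12] = 1
    lv = LabelVolume(labs, {1: "Thin"})
    rep = bm.region_dice_report(lv, lv, ["Thin"], n_slices=50)[0]
    assert rep.slice_indices == [9, 10, 11]


def test_region_dice_report_absent_region_warns():
    ref = _sphere_labels()
    empty = LabelVolume(np.zeros((40, 40, 40), np.int32), {})
    with pytest.warns(RuntimeWarning):
        reports = bm.region_dice_report(empty, ref, ["Sphere"])
    assert reports == []


# ---------------------------------------------------------------------------
# STAPLE

def test_staple_identical_raters_fixed_point():
    rng = np.random.default_rng(1)
    truth = rng.random((32, 32)) < 0.3
    res = bm.staple([truth] * 4)
    assert np.array_equal(res.consensus_mask, truth)
    assert np.all(res.sensitivity > 0.99) and np.all(res.specificity > 0.99)
    assert res.converged


def test_staple_single_dissenter_outvoted():
    rng = np.random.default_rng(2)
    truth = rng.random((32, 32)) < 0.3
    wrong = rng.random((32, 32)) < 0.3
    res = bm.staple([truth, truth, truth, truth, wrong])
    assert bm.dice(res.consensus_mask, truth) > 0.99
    # the dissenter scores visibly lower sensitivity than the faithful raters
    assert res.sensitivity[4] < res.sensitivity[:4].min() - 0.05


def test_staple_validation():
    m = np.zeros((4, 4), bool)
    with pytest.raises(ValidationError):
        bm.staple([m])
    with pytest.raises(ValidationError):
        bm.staple([m, np.zeros((5, 5), bool)])
    with pytest.raises(ValidationError):
        bm.staple([m, m])  # all empty


def test_staple_cross_check_simpleitk():
    sitk = pytest.importorskip("SimpleITK")
    rng = np.random.default_rng(3)
    truth = np.zeros((48, 48), bool)
    truth[12:36, 12:36] = True
    masks = []
    for _ in range(5):
        noisy = truth ^ (rng.random(truth.shape) < 0.08)
        masks.append(noisy)
    ours = bm.staple(masks)
    imgs = [sitk.GetImageFromArray(m.astype(np.uint8)) for m in masks]
    ref_prob = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0))
    ref_mask = ref_prob >= 0.5
    assert bm.dice(ours.consensus_mask, ref_mask) > 0.98


def test_hp_rp_examples():
    truth = np.zeros((32, 32), bool)
    truth[8:24, 8:24] = True
    shifted = np.roll(truth, 2, axis=0)
    study = bm.RaterStudy([truth, truth, truth], shifted)
    hp, rp = bm.hp_rp(study)
    assert all(h == 1.0 for h in hp)
    assert rp == pytest.approx(bm.dice(shifted, truth))
    assert study.staple_result is not None


# ---------------------------------------------------------------------------
# Mann-Whitney U

def test_mwu_worked_examples():
    U, p = bm.mann_whitney_u([1, 2], [3, 4])
    assert U == 0.0 and p == pytest.approx(2 / 6)
    U, p = bm.mann_whitney_u([1, 2], [3, 4], alternative="less")
    assert p == pytest.approx(1 / 6)
    # identical samples: U = n*n/2, p = 1
    U, p = bm.mann_whitney_u([5, 5, 5], [5, 5, 5])
    assert U == 4.5 and p == 1.0


def test_mwu_relabel_invariance():
    a, b = [1.0, 4.0, 2.5], [3.0, 0.5, 5.0]
    U1, p1 = bm.mann_whitney_u(a, b)
    U2, p2 = bm.mann_whitney_u(b, a)
    assert U1 + U2 == len(a) * len(b)
    assert p1 == pytest.approx(p2)


def test_mwu_exact_matches_scipy():
    from scipy.stats import mannwhitneyu
    rng = np.random.default_rng(4)
    for _ in range(20):
        na, nb = rng.integers(2, 7, 2)
        a = rng.integers(0, 5, na).astype(float)
        b = rng.integers(0, 5, nb).astype(float)
        U, p = bm.mann_whitney_u(a, b)
        if np.unique(np.concatenate([a, b])).size == a.size + b.size:
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert U == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-12)
        else:  # scipy has no exact tie handling; compare permutation-style
            ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert U == ref.statistic


def test_mwu_normal_close_to_exact():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        _, p_exact = bm.mann_whitney_u(a, b, exact_limit=12)
        _, p_norm = bm.mann_whitney_u(a, b, exact_limit=0)
        assert abs(p_exact - p_norm) < 0.05


def test_mwu_validation():
    with pytest.raises(ValidationError):
        bm.mann_whitney_u([], [1.0])
    with pytest.raises(ValidationError):
        bm.mann_whitney_u([1.0], [2.0], alternative="sideways")


# ---------------------------------------------------------------------------
# landmarks

def test_landmark_distances_345():
    pairs = [((0, 0, 0), (3, 4, 0)), ((1, 1, 1), (1, 1, 1)), ((0, 0, 0), (0, 0, 2))]
    d, med = bm.landmark_distances(pairs)
    assert np.allclose(d, [5.0, 0.0, 2.0])
    assert med == 2.0
    # independent recount
    assert d[0] == pytest.approx(np.sqrt(3 ** 2 + 4 ** 2))
    with pytest.raises(ValidationError):
        bm.landmark_distances([])
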