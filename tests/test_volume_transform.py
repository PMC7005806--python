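import numpy as np
import pytest

import brainsmapi as bm
from brainsmapi.types import AffineTransform, DisplacementField, ValidationError, Volume3D
from brainsmapi.volume_transform import default_margin


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mapping(rng, low_shape=(16, 16, 16), s=2.0, amplitude=1.5):
    m = np.eye(4)
    m[:3, :3] += rng.normal(0, 0.03, (3, 3))
    m[3, :3] = rng.normal(0, 2.0, 3)
    M = AffineTransform(m)
    phi = DisplacementField(np.asarray(
        bm.make_synthetic_field(low_shape, amplitude, 6.0,
                                seed=int(rng.integers(1 << 30))).field.components))
    out_shape = tuple(int(round(n * s)) for n in low_shape)
    return bm.HighResMapping.from_lowres(M, phi, s, out_shape)


# ---------------------------------------------------------------------------
# coordinate-mapping micro-oracles

def test_scale_affine_trivial_cases():
    I = AffineTransform.identity(3)
    assert np.allclose(bm.scale_affine(I, 32.0).matrix, np.eye(4))
    m = np.eye(4)
    m[3, :3] = [1.0, -2.0, 3.0]
    out = bm.scale_affine(AffineTransform(m), 4.0)
    assert np.allclose(out.translation, [4.0, -8.0, 12.0])
    assert np.allclose(out.linear, np.eye(3))
    with pytest.raises(ValidationError):
        bm.scale_affine(I, -2.0)


def test_scale_affine_commutation(rng):
    m = np.eye(4)
    m[:3, :3] += rng.normal(0, 0.2, (3, 3))
    m[3, :3] = rng.normal(0, 10, 3)
    M = AffineTransform(m)
    s = 32.0
    Mp = bm.scale_affine(M, s)
    p = rng.random((100, 3)) * 50
    err = np.abs(Mp.apply(s * p) - s * M.apply(p))
    assert err.max() < 1e-6


def test_interp_field_independent_expansion(rng):
    """interp_field vs a from-scratch 8-corner trilinear expansion."""
    comps = rng.standard_normal((3, 9, 10, 11))
    f = DisplacementField(comps)
    q = rng.uniform(0, 8, (1000, 3)) * np.array([1.0, 9 / 8, 10 / 8])
    got = bm.interp_field(f, q)
    i0 = np.floor(q).astype(int)
    x0, y0, z0 = (q - i0).T
    expect = np.zeros_like(got)
    for d in range(3):
        phi = comps[d]
        c = lambda dx, dy, dz: phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        expect[:, d] = ((1 - x0) * (1 - y0) * (1 - z0) * c(0, 0, 0)
                        + x0 * (1 - y0) * (1 - z0) * c(1, 0, 0)
                        + (1 - x0) * y0 * (1 - z0) * c(0, 1, 0)
                        + (1 - x0) * (1 - y0) * z0 * c(0, 0, 1)
                        + x0 * y0 * (1 - z0) * c(1, 1, 0)
                        + x0 * (1 - y0) * z0 * c(1, 0, 1)
                        + (1 - x0) * y0 * z0 * c(0, 1, 1)
                        + x0 * y0 * z0 * c(1, 1, 1))
    assert np.abs(got - expect).max() < 1e-12


def test_interp_field_nodes_clamp_and_nan(rng):
    comps = rng.standard_normal((3, 5, 5, 5))
    f = DisplacementField(comps)
    assert np.allclose(bm.interp_field(f, [[2.0, 3.0, 4.0]])[0], comps[:, 2, 3, 4])
    # clamp: far outside equals the boundary vector
    assert np.allclose(bm.interp_field(f, [[-10.0, 0.0, 0.0]])[0], comps[:, 0, 0, 0])
    with pytest.raises(ValidationError):
        bm.interp_field(f, [[np.nan, 0.0, 0.0]])


def test_map_point_trivial_and_scaled(rng):
    zero = DisplacementField.zeros((8, 8, 8))
    ident = bm.HighResMapping.from_lowres(AffineTransform.identity(3), zero, 4.0,
                                          (32, 32, 32))
    P = rng.random((50, 3)) * 31
    assert np.abs(bm.map_point(ident, P) - P).max() < 1e-12
    const = DisplacementField(np.full((3, 8, 8, 8), 0.75))
    m = bm.HighResMapping.from_lowres(AffineTransform.identity(3), const, 4.0,
                                      (32, 32, 32))
    assert np.allclose(bm.map_point(m, P), P + 4.0 * 0.75)


def test_map_point_scale_commutation_oracle(rng):
    mapping = random_mapping(rng, s=8.0)
    s = 8.0
    P = rng.random((200, 3)) * (np.array(mapping.out_shape) - 1)
    # low-res mapping applied at P/s, then amplified by s
    M_low = AffineTransform(np.diag([s, s, s, 1.0]) @ mapping.M_prime.matrix
                            @ np.diag([1 / s, 1 / s, 1 / s, 1.0]))
    low = M_low.apply(P / s) + bm.interp_field(mapping.field, P / s)
    assert np.abs(bm.map_point(mapping, P) - s * low).max() < 1e-9


# ---------------------------------------------------------------------------
# blocks and ROIs

def test_plan_blocks_counts():
    assert bm.plan_blocks((100, 100, 100), 64).n_blocks == (2, 2, 2)
    g = bm.plan_blocks((64, 64, 64), 64)
    assert g.n_blocks == (1, 1, 1) and g.extent((0, 0, 0)) == ((0, 64), (0, 64), (0, 64))
    with pytest.raises(ValidationError):
        bm.plan_blocks((64, 64, 64), 4)


def test_roi_identity_and_shift(rng):
    zero = DisplacementField.zeros((16, 16, 16))
    ident = bm.HighResMapping.from_lowres(AffineTransform.identity(3), zero, 1.0,
                                          (16, 16, 16))
    roi, _ = bm.roi_for_block(((0, 8), (0, 8), (0, 8)), ident, margin=0)
    assert roi == ((0, 8), (0, 8), (0, 8))
    m = np.eye(4)
    m[3, :3] = [3.0, 0.0, 0.0]
    shifted = bm.HighResMapping.from_lowres(AffineTransform(m), zero, 1.0, (16, 16, 16))
    roi, _ = bm.roi_for_block(((0, 8), (0, 8), (0, 8)), shifted, margin=0)
    assert roi[0] == (3, 11)


def test_roi_containment_exhaustive(rng):
    """With the default margin, every voxel's source lies inside its block ROI."""
    mapping = random_mapping(rng, low_shape=(16, 16, 16), s=2.0, amplitude=2.0)
    margin = default_margin(2.0)
    for extent in [((0, 32), (0, 32), (0, 32)), ((8, 24), (0, 16), (16, 32))]:
        roi, _ = bm.roi_for_block(extent, mapping, margin=margin)
        grids = np.meshgrid(*[np.arange(lo, hi, dtype=float) for lo, hi in extent],
                            indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        mapped = bm.map_point(mapping, pts)
        for a in range(3):
            assert mapped[:, a].min() >= roi[a][0]
            assert mapped[:, a].max() <= roi[a][1] - 1


def test_roi_outside_source_is_empty():
    zero = DisplacementField.zeros((16, 16, 16))
    m = np.eye(4)
    m[3, :3] = [500.0, 0.0, 0.0]
    mapping = bm.HighResMapping.from_lowres(AffineTransform(m), zero, 1.0, (16, 16, 16))
    roi, idx = bm.roi_for_block(((0, 16), (0, 16), (0, 16)), mapping, margin=2,
                                src_shape=(16, 16, 16), src_block_size=(8, 8, 8))
    assert roi is None and idx == set()


# ---------------------------------------------------------------------------
# block transforms

def _stored(tmp_path, rng, shape, name="src", block=8):
    v = Volume3D(rng.integers(0, 255, shape).astype(np.uint8))
    store = bm.create_block_store(shape, block, np.uint8, root=tmp_path / name)
    bm.ingest_volume(store, v)
    return v, store


def test_transform_block_identity_bit_exact(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (16, 16, 16))
    zero = DisplacementField.zeros((16, 16, 16))
    ident = bm.HighResMapping.from_lowres(AffineTransform.identity(3), zero, 1.0,
                                          (16, 16, 16))
    for interp in ("nearest", "linear"):
        blk = bm.transform_block(((0, 8), (8, 16), (0, 8)), store, ident, interp=interp)
        assert np.array_equal(blk, v.data[0:8, 8:16, 0:8])


def test_transform_volume_identity_and_workers(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (24, 24, 24))
    zero = DisplacementField.zeros((24, 24, 24))
    ident = bm.HighResMapping.from_lowres(AffineTransform.identity(3), zero, 1.0,
                                          (24, 24, 24))
    outs = {}
    for workers in (1, 4):
        out = bm.create_block_store((24, 24, 24), 8, np.uint8,
                                    root=tmp_path / f"o{workers}")
        stats = bm.transform_volume(store, ident, out, interp="nearest",
                                    workers=workers)
        assert stats.blocks_total == 27 and stats.containment_violations == 0
        outs[workers] = bm.assemble_volume(out).data
    assert np.array_equal(outs[1], v.data)
    assert np.array_equal(outs[1], outs[4])


def test_blockwise_equals_dense_oracle(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (40, 36, 44), block=16)
    mapping = random_mapping(rng, low_shape=(20, 18, 22), s=2.0)
    for interp in ("nearest", "linear"):
        dense = bm.transform_volume_dense(v, mapping, interp=interp)
        out = bm.create_block_store(mapping.out_shape, (16, 32, 8), np.uint8,
                                    root=tmp_path / f"out_{interp}")
        bm.transform_volume(store, mapping, out, interp=interp)
        assert np.array_equal(bm.assemble_volume(out).data, dense.data)


def test_blockwise_equals_lowres_oracle(tmp_path, rng):
    """At s = 1 the block path reproduces apply_transform_lowres (nearest)."""
    vol, labs = bm.make_synthetic_brain(shape=(32, 32, 32), n_regions=3, seed=3)
    M = AffineTransform.identity(3)
    phi = DisplacementField(np.asarray(
        bm.make_synthetic_field((32, 32, 32), 2.0, 8.0, seed=4).field.components))
    oracle = bm.apply_transform_lowres(labs, M, phi)
    store = bm.create_block_store((32, 32, 32), 16, np.int32, root=tmp_path / "lab")
    bm.ingest_volume(store, Volume3D(labs.labels))
    mapping = bm.HighResMapping.from_lowres(M, phi, 1.0, (32, 32, 32))
    out = bm.create_block_store((32, 32, 32), 16, np.int32, root=tmp_path / "out")
    bm.transform_volume(store, mapping, out, interp="nearest")
    got = bm.assemble_volume(out).data
    assert np.array_equal(got, oracle.labels)
    assert set(np.unique(got)).issubset(set(np.unique(labs.labels)))


def test_brain_mask_skipping(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (32, 32, 32))
    zero = DisplacementField.zeros((32, 32, 32))
    ident = bm.HighResMapping.from_lowres(AffineTransform.identity(3), zero, 1.0,
                                          (32, 32, 32))
    mask = np.zeros((32, 32, 32), dtype=bool)
    mask[:8, :8, :8] = True
    out = bm.create_block_store((32, 32, 32), 8, np.uint8, root=tmp_path / "o")
    stats = bm.transform_volume(store, ident, out, interp="nearest",
                                brain_mask=mask)
    assert stats.blocks_skipped > 0
    got = bm.assemble_volume(out).data
    assert np.array_equal(got[:8, :8, :8], v.data[:8, :8, :8])


def test_transform_stats_histogram(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (32, 32, 32), block=8)
    mapping = random_mapping(rng, low_shape=(16, 16, 16), s=2.0)
    out = bm.create_block_store((32, 32, 32), 16, np.uint8, root=tmp_path / "o")
    stats = bm.transform_volume(store, mapping, out)
    assert stats.blocks_total == 8
    assert sum(stats.src_blocks_loaded.values()) == stats.blocks_total
    assert stats.max_roi_blocks == max(stats.src_blocks_loaded)


def test_reslice_roundtrip_and_errors(tmp_path, rng):
    v, store = _stored(tmp_path, rng, (10, 12, 14))
    import tifffile
    for axis, a in (("x", 0), ("y", 1), ("z", 2)):
        paths = bm.reslice(store, axis, tmp_path / f"sl_{axis}")
        assert len(paths) == v.shape[a]
        stacked = np.stack([tifffile.imread(p) for p in paths], axis=a)
        assert np.array_equal(stacked, v.data)
    with pytest.raises(ValidationError):
        bm.reslice(store, "w", tmp_path / "bad")
    # incomplete store errors and names missing blocks
    incomplete = bm.create_block_store((16, 16, 16), 8, np.uint8,
                                       root=tmp_path / "inc")
    bm.write_block(incomplete, (0, 0, 0), np.zeros((8, 8, 8), np.uint8))
    with pytest.raises(IOError, match="missing"):
        bm.reslice(incomplete, "z", tmp_path / "never")


def test_reslice_single_voxel_placement(tmp_path):
    store = bm.create_block_store((8, 8, 8), 8, np.uint8, root=tmp_path / "s")
    data = np.zeros((8, 8, 8), np.uint8)
    data[3, 4, 5] = 77
    bm.write_block(store, (0, 0, 0), data)
    import tifffile
    paths = bm.reslice(store, "z", tmp_path / "sl")
    sl = tifffile.imread(paths[5])
    assert sl[3, 4] == 77 and sl.sum() == 77
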