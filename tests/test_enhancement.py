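import numpy as np
import pytest
from scipy import ndimage

from nucleovit.enhancement import (EdgeMap, NormalizationConstants,
                                   OracleSegmenter, canny_on_mask,
                                   channel_difference_view, denormalize,
                                   enhance_dataset, fuse_edges,
                                   normalize_for_classifier,
                                   resize_to_multiple)
from nucleovit.synthetic import (benign_spec, generate_dataset, load_image,
                                 load_mask, malignant_spec, read_manifest)


def boundary_band(mask, width=1):
    """Oracle: pixels within `width` of a 0/1 transition of the mask."""
    mask = mask.astype(bool)
    edge = mask ^ ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) ^ mask
    return ndimage.binary_dilation(edge | outer, iterations=width)


# ------------------------------------------------------------------ resize

def test_resize_breakhis_dims():
    img = np.zeros((700, 460, 3), dtype=np.uint8)
    assert resize_to_multiple(img).shape == (704, 448, 3)


def test_resize_already_divisible_unchanged():
    img = np.arange(64 * 64 * 3, dtype=np.uint8).reshape(64, 64, 3)
    out = resize_to_multiple(img)
    assert out is img


def test_resize_minimum_clamp():
    assert resize_to_multiple(np.zeros((10, 10, 3), np.uint8)).shape == (32, 32, 3)


def test_resize_bad_multiple():
    with pytest.raises(ValueError):
        resize_to_multiple(np.zeros((64, 64, 3), np.uint8), multiple=0)


# ------------------------------------------------------------------- canny

def test_canny_empty_mask():
    assert canny_on_mask(np.zeros((32, 32), np.uint8)).values.sum() == 0


def test_canny_full_mask_no_gradient():
    assert canny_on_mask(np.ones((32, 32), np.uint8)).values.sum() == 0


def test_canny_rejects_raw_image():
    with pytest.raises(ValueError, match="binary"):
        canny_on_mask(np.full((16, 16), 128, np.uint8))


def test_canny_square_ring_matches_morphological_boundary():
    mask = np.zeros((64, 64), np.uint8)
    mask[22:42, 22:42] = 1
    em = canny_on_mask(mask)
    boundary = mask & ~ndimage.binary_erosion(mask)
    # single closed ring
    _, n = ndimage.label(em.values, structure=np.ones((3, 3)))
    assert n == 1
    # mutual 1-px containment with the morphological boundary
    d_to_boundary = ndimage.distance_transform_edt(~boundary.astype(bool))
    assert (d_to_boundary[em.values == 1] <= np.sqrt(2)).all()
    d_to_edges = ndimage.distance_transform_edt(em.values == 0)
    assert (d_to_edges[boundary == 1] <= np.sqrt(2)).all()


def test_edge_pixels_within_boundary_band_property():
    from nucleovit.synthetic import generate_sample

    for seed in range(5):
        mask = generate_sample(malignant_spec(seed=seed)).mask
        em = canny_on_mask(mask)
        band = boundary_band(mask)
        assert (band[em.values == 1]).all()


def test_edgemap_rejects_non_binary():
    with pytest.raises(ValueError):
        EdgeMap(values=np.full((4, 4), 3, np.uint8))


# -------------------------------------------------------------------- fuse

def test_fuse_empty_edgemap_identity():
    img = np.random.default_rng(0).integers(0, 256, (32, 32, 3), np.uint8)
    out = fuse_edges(img, np.zeros((32, 32), np.uint8), edge_gain=0.0)
    assert out.tobytes() == img.tobytes()


def test_fuse_gain_zero_blackens_edges_only():
    img = np.random.default_rng(1).integers(1, 256, (16, 16, 3), np.uint8)
    edges = np.zeros((16, 16), np.uint8)
    edges[5, 5] = edges[10, 2] = 1
    out = fuse_edges(img, edges, 0.0)
    assert (out[edges == 1] == 0).all()
    assert np.array_equal(out[edges == 0], img[edges == 0])


def test_fuse_gain_half_direct_multiplication():
    img = np.zeros((4, 4, 3), np.uint8)
    img[1, 1] = (200, 100, 50)
    edges = np.zeros((4, 4), np.uint8)
    edges[1, 1] = 1
    out = fuse_edges(img, edges, 0.5)
    assert tuple(out[1, 1]) == (100, 50, 25)


def test_fuse_shape_mismatch():
    with pytest.raises(ValueError):
        fuse_edges(np.zeros((8, 8, 3), np.uint8), np.zeros((4, 4), np.uint8))


def test_fuse_idempotent_at_gain_zero():
    img = np.random.default_rng(2).integers(0, 256, (16, 16, 3), np.uint8)
    edges = (np.random.default_rng(3).random((16, 16)) > 0.8).astype(np.uint8)
    once = fuse_edges(img, edges, 0.0)
    twice = fuse_edges(once, edges, 0.0)
    assert np.array_equal(once, twice)


# --------------------------------------------------------------- normalize

def test_normalize_channel0_white():
    img = np.full((32, 32, 3), 255, np.uint8)
    out = normalize_for_classifier(img)
    assert out.shape == (3, 32, 32)
    assert out[0, 0, 0] == pytest.approx((1.0 - 0.485) / 0.229, rel=1e-4)


def test_normalize_mean_centering_zero():
    arr = np.zeros((8, 8, 3))
    arr[..., 0] = 0.485 * 255
    out = normalize_for_classifier(arr.astype(np.float64))
    # non-integer pixel values allowed for this arithmetic check
    assert np.abs(out[0]).max() < 1e-12


def test_normalize_inverse_recovers():
    img = np.random.default_rng(4).integers(0, 256, (16, 16, 3), np.uint8)
    rec = denormalize(normalize_for_classifier(img))
    assert np.abs(rec - img.transpose(2, 0, 1) / 255.0).max() <= 1e-6


def test_normalize_wrong_channels():
    with pytest.raises(ValueError):
        normalize_for_classifier(np.zeros((16, 16), np.uint8))


def test_constants_validation():
    with pytest.raises(ValueError):
        NormalizationConstants(std=(0.0, 0.1, 0.1))


# ----------------------------------------------------------------- dataset

@pytest.fixture(scope="module")
def synth_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("enh")
    return generate_dataset(8, benign_spec(), malignant_spec(), 17, out / "d")


def _oracle_from_manifest(manifest):
    return OracleSegmenter({r["id"]: load_mask(r["mask"])
                            for r in read_manifest(manifest)})


def test_enhance_dataset_dims_and_count(synth_manifest, tmp_path):
    seg = _oracle_from_manifest(synth_manifest)
    out_manifest = enhance_dataset(synth_manifest, seg, tmp_path / "out")
    rows = read_manifest(out_manifest)
    assert len(rows) == 16
    for row in rows:
        assert row["error"] == ""
        img = load_image(row["image"])
        assert img.shape[0] % 32 == 0 and img.shape[1] % 32 == 0


def test_enhance_locality_with_oracle_masks(synth_manifest, tmp_path):
    seg = _oracle_from_manifest(synth_manifest)
    out_manifest = enhance_dataset(synth_manifest, seg, tmp_path / "loc")
    for row in read_manifest(out_manifest):
        original = load_image(row["original"])
        enhanced = load_image(row["image"])
        mask = seg.mask_by_key[row["id"]]
        diff = np.any(original != enhanced, axis=-1)
        assert not diff[~boundary_band(mask)].any()


def test_enhance_rerun_byte_identical(synth_manifest, tmp_path):
    seg = _oracle_from_manifest(synth_manifest)
    m1 = enhance_dataset(synth_manifest, seg, tmp_path / "a")
    m2 = enhance_dataset(synth_manifest, seg, tmp_path / "b")
    for r1, r2 in zip(read_manifest(m1), read_manifest(m2)):
        assert open(r1["image"], "rb").read() == open(r2["image"], "rb").read()


def test_enhance_missing_file_recorded_run_continues(synth_manifest, tmp_path):
    rows = read_manifest(synth_manifest)
    rows[0] = dict(rows[0], image=str(tmp_path / "nope.png"))
    seg = _oracle_from_manifest(synth_manifest)
    out_manifest = enhance_dataset(rows, seg, tmp_path / "err")
    out_rows = read_manifest(out_manifest)
    assert out_rows[0]["error"] != ""
    assert all(r["error"] == "" for r in out_rows[1:])


def test_enhance_image_identity_segmenter_edge_count_logged(synth_manifest, tmp_path):
    seg = _oracle_from_manifest(synth_manifest)
    out_manifest = enhance_dataset(synth_manifest, seg, tmp_path / "cnt")
    for row in read_manifest(out_manifest):
        assert int(row["edge_pixels"]) > 0


# -------------------------------------------------------------- difference

def test_channel_difference_identical_inputs_zero_panel():
    img = np.random.default_rng(5).integers(0, 256, (32, 32, 3), np.uint8)
    n = normalize_for_classifier(img)
    panel = channel_difference_view(n, n)
    assert panel.shape == (32, 96)
    assert (panel[:, 64:] == 0).all()


def test_channel_difference_nonzero_exactly_on_edges():
    img = np.random.default_rng(6).integers(10, 246, (32, 32, 3), np.uint8)
    edges = np.zeros((32, 32), np.uint8)
    edges[8:12, 8:12] = 1
    fused = fuse_edges(img, edges, 0.0)
    o = normalize_for_classifier(img)
    e = normalize_for_classifier(fused)
    diff = np.abs(e[2] - o[2]) > 0
    assert np.array_equal(diff, edges.astype(bool))


def test_channel_difference_bad_channel():
    n = normalize_for_classifier(np.zeros((32, 32, 3), np.uint8))
    with pytest.raises(IndexError):
        channel_difference_view(n, n, channel_index=7)
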