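import numpy as np
import pytest

from octdme.features import (
    DEFAULT_PARTITION,
    DescriptorConfig,
    HOGDescriptor,
    LBPDescriptor,
    descriptor_length,
    extract_descriptor,
    gaussian_pyramid,
    hog_descriptor,
    lbp_code_image,
    lbp_descriptor,
    lbp_pattern_count,
    pyramid_dims,
)

from oracles import brute_lbp


# ---------------------------------------------------------------------------
# pyramid

def test_pyramid_dims_floor_halving():
    pyr = gaussian_pyramid(np.zeros((356, 340)), 4)
    assert [p.shape for p in pyr] == [(356, 340), (178, 170), (89, 85), (44, 42)]
    assert pyramid_dims((356, 340), 4) == [(356, 340), (178, 170), (89, 85), (44, 42)]


def test_pyramid_constant_and_single_level(rng):
    c = np.full((64, 64), 0.4)
    for lvl in gaussian_pyramid(c, 4):
        np.testing.assert_allclose(lvl, 0.4, atol=1e-12)
    img = rng.random((32, 32))
    assert gaussian_pyramid(img, 1)[0] is img or np.array_equal(gaussian_pyramid(img, 1)[0], img)


def test_pyramid_too_small_raises():
    with pytest.raises(ValueError):
        gaussian_pyramid(np.zeros((10, 10)), 4)


# ---------------------------------------------------------------------------
# LBP

@pytest.mark.parametrize("P,expected", [(8, 10), (16, 18), (24, 26), (4, 6)])
def test_ri_pattern_counts(P, expected):
    assert lbp_pattern_count(P, "ri") == expected


@pytest.mark.parametrize("P", [8, 16, 24])
def test_nri_pattern_counts(P):
    assert lbp_pattern_count(P, "nri") == P * (P - 1) + 3


def test_pattern_count_validates():
    with pytest.raises(ValueError):
        lbp_pattern_count(3, "ri")


def test_constant_image_single_uniform_class():
    """Ties (neighbor == center) count as 1: constant input is all-ones everywhere."""
    c = np.full((16, 16), 0.5)
    for P, R in ((8, 1), (16, 2)):
        codes = lbp_code_image(c, P, R, "ri")
        interior = codes[R:-R, R:-R]
        assert (interior == P).all()  # popcount of the all-ones pattern
        nri = lbp_code_image(c, P, R, "nri")[R:-R, R:-R]
        assert (nri == 1).all()  # label 1 reserved for all-ones


@pytest.mark.parametrize("P,R", [(8, 1), (16, 2), (24, 3)])
@pytest.mark.parametrize("variant", ["ri", "nri"])
def test_lbp_matches_brute_force(P, R, variant, rng):
    img = rng.random((12, 12))
    np.testing.assert_array_equal(lbp_code_image(img, P, R, variant), brute_lbp(img, P, R, variant))


def test_lbp_matches_skimage_riu2(rng):
    """Interior riu2 codes agree with the independent scikit-image implementation."""
    from skimage.feature import local_binary_pattern

    img = rng.random((20, 20))
    for P, R in ((8, 1), (16, 2), (24, 3)):
        mine = lbp_code_image(img, P, R, "ri")[R:-R, R:-R]
        theirs = local_binary_pattern(img, P, R, "uniform")[R:-R, R:-R]
        np.testing.assert_array_equal(mine, theirs.astype(int))


def test_lbp_rotation_invariance(rng):
    """Full-image RI histograms of an image and its 90-degree rotation agree within 2%."""
    img = rng.random((64, 64))
    for P, R in ((8, 1), (16, 2)):
        h = []
        for im in (img, np.rot90(img)):
            codes = lbp_code_image(im, P, R, "ri")
            valid = codes[codes >= 0]
            hist = np.bincount(valid, minlength=P + 2).astype(float)
            h.append(hist / hist.sum())
        assert np.abs(h[0] - h[1]).sum() <= 0.02


def test_lbp_small_image_raises():
    with pytest.raises(ValueError):
        lbp_code_image(np.zeros((4, 4)), 16, 2)


@pytest.mark.parametrize(
    "P,R,expected", [(8, 1, 180), (16, 2, 324), (24, 3, 468)]
)
def test_lbp_descriptor_lengths_on_cropped_geometry(P, R, expected, rng):
    """Default 18-patch partition reproduces the canonical per-B-scan sizes."""
    img = rng.random((356, 340))
    vec = lbp_descriptor(gaussian_pyramid(img, 4), P, R, "ri")
    assert vec.shape == (expected,)
    cfg = DescriptorConfig("lbp-ri", P, R)
    assert descriptor_length(cfg, (356, 340)) == expected


def test_lbp_histograms_l1_normalized(rng):
    img = rng.random((128, 128))
    vec = lbp_descriptor(gaussian_pyramid(img, 4), 8, 1, "ri")
    n_patches = sum(g[0] * g[1] for g in DEFAULT_PARTITION)
    hists = vec.reshape(n_patches, 10)
    np.testing.assert_allclose(hists.sum(axis=1), 1.0, atol=1e-9)
    assert (vec >= 0).all()


def test_lbp_constant_input_one_hot_patches():
    vec = lbp_descriptor(gaussian_pyramid(np.full((128, 128), 0.3), 4), 8, 1, "ri")
    n_patches = sum(g[0] * g[1] for g in DEFAULT_PARTITION)
    assert vec.sum() == pytest.approx(n_patches)
    hists = vec.reshape(n_patches, 10)
    assert ((hists == 0) | (hists == 1)).all()


def test_tiles32_mode_length(rng):
    """Literal 32 px tiling: patch count follows floor(h/32) * floor(w/32) per level."""
    img = rng.random((128, 128))
    cfg = DescriptorConfig("lbp-ri", 8, 1, patch_mode="tiles32")
    vec = extract_descriptor(img, cfg)
    expected_patches = sum((r // 32) * (c // 32) for r, c in pyramid_dims((128, 128), 4))
    assert vec.shape == (expected_patches * 10,)
    assert descriptor_length(cfg, (128, 128)) == vec.size


# ---------------------------------------------------------------------------
# HoG

def test_hog_canonical_level_sizes(rng):
    img = rng.random((356, 340))
    pyr = gaussian_pyramid(img, 4)
    from octdme.features import _hog_single_level

    sizes = [_hog_single_level(lvl, 4, 2, 9).size for lvl in pyr]
    assert sizes == [266112, 63468, 15120, 3240]
    assert hog_descriptor(pyr).size == 347940
    assert descriptor_length(DescriptorConfig("hog"), (356, 340)) == 347940


def test_hog_minimal_geometry(rng):
    """An 8x8 image gives 2x2 cells, one block, 36 values with L2 norm <= 1."""
    vec = hog_descriptor([rng.random((8, 8))])
    assert vec.shape == (36,)
    assert np.linalg.norm(vec) <= 1.0 + 1e-6


def test_hog_block_norms_bounded(rng):
    vec = hog_descriptor([rng.random((32, 32))])
    blocks = vec.reshape(-1, 36)
    assert (np.linalg.norm(blocks, axis=1) <= 1.0 + 1e-6).all()


def test_hog_orientation_binning():
    """A pure vertical edge puts gradient energy in the horizontal-gradient bin."""
    img = np.tile(np.linspace(0, 1, 16), (16, 1))  # constant horizontal ramp
    vec = hog_descriptor([img]).reshape(-1, 4, 9)
    energy = vec.sum(axis=(0, 1))
    assert energy.argmax() == 0  # orientation 0 = horizontal gradient direction


def test_hog_too_small_raises():
    with pytest.raises(ValueError):
        hog_descriptor([np.zeros((6, 6))])


# ---------------------------------------------------------------------------
# length invariant across configs

@pytest.mark.parametrize(
    "cfg,shape",
    [
        (DescriptorConfig("lbp-ri", 8, 1), (96, 128)),
        (DescriptorConfig("lbp-nri", 16, 2), (160, 160)),
        (DescriptorConfig("hog"), (96, 128)),
        (DescriptorConfig("lbp-ri", 24, 3, patch_mode="tiles32"), (160, 192)),
    ],
)
def test_extract_length_matches_closed_form(cfg, shape, rng):
    img = rng.random(shape)
    assert extract_descriptor(img, cfg).size == descriptor_length(cfg, shape)


def test_sklearn_transformer_api(rng):
    imgs = rng.random((3, 96, 128))
    lbp = LBPDescriptor(points=8, radius=1)
    X = lbp.fit_transform(imgs)
    assert X.shape == (3, 180)
    assert lbp.get_params()["points"] == 8
    hog = HOGDescriptor().set_params(levels=2)
    assert hog.fit_transform(imgs).shape[0] == 3
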