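import numpy as np
import pytest
from skimage.feature import graycomatrix

from _oracles import brute_glcm, brute_haralick13, brute_lbp_hist

from locfuse import (
    FeatureVector,
    aggregate_patches,
    deep_embed,
    haralick26,
    lbp_histogram,
    quantize_gray,
    wavelet_haralick,
)
from locfuse.embeddings import EmbeddingContractError, SeededConvEmbedding
from locfuse.img_features import (
    GLCM_OFFSETS,
    PatchSizeError,
    glcm,
    haralick_statistics,
)


# ------------------------------------------------------------- quantization


def test_quantize_constant_patch_all_zero():
    assert np.all(quantize_gray(np.full((8, 8), 7.0)) == 0)


def test_quantize_ramp_equal_width_bands():
    ramp = np.tile(np.arange(256.0), (4, 1))
    q = quantize_gray(ramp, 32)
    widths = np.bincount(q.ravel(), minlength=32) / 4
    assert set(q.ravel()) == set(range(32))
    assert widths.max() - widths.min() <= 1


def test_quantize_range_contract(rng):
    q = quantize_gray(rng.uniform(-50, 300, size=(16, 16)))
    assert q.min() >= 0 and q.max() <= 31


# --------------------------------------------------------------------- GLCM


def test_glcm_normalized_symmetric_and_matches_skimage(rng):
    q = quantize_gray(rng.uniform(0, 255, size=(12, 12)))
    # skimage angles step (sin t, cos t) in (row, col), i.e. downward rows, so
    # its pi/4 offset (+1, +1) is this package's 135-degree direction
    angles = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
    for direction, angle in angles.items():
        mine = glcm(q, direction)
        assert mine.sum() == pytest.approx(1.0)
        assert np.allclose(mine, mine.T)
        ref = graycomatrix(
            q, [1], [angle], levels=32, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(mine, ref, rtol=1e-12, atol=1e-15)


# ----------------------------------------------------------------- Haralick


def test_constant_patch_degenerate_haralick_values():
    out = haralick26(np.full((16, 16), 42.0))
    means, ranges = out[:13], out[13:]
    assert means[0] == 1.0  # ASM
    assert means[1] == 0.0  # contrast
    assert means[2] == 0.0  # correlation, defined 0 at zero variance
    assert means[8] == 0.0  # entropy
    assert np.all(ranges == 0)


def test_checkerboard_contrast_by_direction():
    board = np.indices((8, 8)).sum(axis=0) % 2 * 31.0
    q = quantize_gray(board)
    per_dir = {d: haralick_statistics(glcm(q, d)) for d in GLCM_OFFSETS}
    # horizontal/vertical neighbors always differ by 31 levels; one diagonal
    # direction always matches (contrast 0)
    assert per_dir[0][1] == pytest.approx(31**2)
    assert per_dir[90][1] == pytest.approx(31**2)
    assert min(per_dir[45][1], per_dir[135][1]) == pytest.approx(0.0)
    # hand-built GLCM of the periodic pattern: all mass on (0,31)/(31,0)
    expected = np.zeros((32, 32))
    expected[0, 31] = expected[31, 0] = 0.5
    np.testing.assert_allclose(glcm(q, 0), expected)


def test_haralick26_matches_brute_force_on_random_patches(rng):
    for _ in range(20):
        patch = rng.uniform(0, 255, size=(8, 8))
        q = quantize_gray(patch)
        stats = np.vstack(
            [brute_haralick13(brute_glcm(q, *GLCM_OFFSETS[d])) for d in GLCM_OFFSETS]
        )
        expected = np.concatenate(
            [stats.mean(axis=0), stats.max(axis=0) - stats.min(axis=0)]
        )
        np.testing.assert_allclose(haralick26(patch), expected, rtol=1e-9, atol=1e-12)


def test_rotation_by_90_degrees_preserves_direction_means(rng):
    patch = rng.uniform(0, 255, size=(16, 16))
    a = haralick26(patch)[:13]
    b = haralick26(np.rot90(patch))[:13]
    np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


# ------------------------------------------------------------------ wavelets


def test_wavelet_haralick_dimension_formula(one_patch):
    assert wavelet_haralick(one_patch).size == 674
    small = np.random.default_rng(1).uniform(0, 255, (64, 64))
    for levels in (2, 4):
        assert wavelet_haralick(small, levels=levels).size == 3 * 27 * levels + 26


def test_wavelet_haralick_constant_patch_degenerate():
    out = wavelet_haralick(np.full((64, 64), 9.0), levels=3)
    # per-band blocks: 26 stats + 1 energy; all energies 0, ASM 1, entropy 0
    for band in range(9):
        block = out[26 + 27 * band : 26 + 27 * (band + 1)]
        assert block[26] == pytest.approx(0.0, abs=1e-20)  # band energy
        assert block[0] == 1.0 and block[8] == 0.0


def test_horizontal_stripes_energize_horizontal_bands():
    img = np.zeros((128, 128))
    img[::8, :] = 255.0
    out = wavelet_haralick(img, wavelet="db2", levels=4)
    h_energy = [out[26 + 27 * (3 * lev + 0) + 26] for lev in range(4)]
    v_energy = [out[26 + 27 * (3 * lev + 1) + 26] for lev in range(4)]
    assert sum(h_energy) > 100 * sum(v_energy)


def test_unsupported_wavelet_rejected(one_patch):
    with pytest.raises(ValueError, match="db1..db10"):
        wavelet_haralick(one_patch, wavelet="haar")


# ----------------------------------------------------------------------- LBP


def test_lbp_constant_patch_all_codes_255():
    hist = lbp_histogram(np.full((10, 10), 3.0))
    assert hist[255] == 1.0 and hist.sum() == 1.0


def test_lbp_hand_assembled_3x3_code():
    patch = np.array([[20, 5, 5], [5, 10, 5], [5, 5, 20]], dtype=float)
    # neighbors clockwise from top-left: 20,5,5,5,20,5,5,5 -> bits 10001000
    hist = lbp_histogram(patch)
    assert hist[0b10001000] == 1.0


def test_lbp_spec_neighbor_order_example():
    # center 10; clockwise-from-top-left neighbor values (20,5,5,5,5,5,5,20)
    patch = np.array([[20, 5, 5], [20, 10, 5], [5, 5, 5]], dtype=float)
    hist = lbp_histogram(patch)
    assert hist[129] == 1.0


def test_lbp_invariant_to_additive_shift(rng):
    patch = rng.uniform(0, 200, size=(12, 12))
    np.testing.assert_array_equal(lbp_histogram(patch), lbp_histogram(patch + 37.0))


def test_lbp_matches_brute_force(rng):
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    for _ in range(20):
        patch = rng.integers(0, 8, size=(6, 6)).astype(float)
        expected = np.zeros(256)
        for r in range(1, 5):
            for c in range(1, 5):
                code = 0
                for k, (dr, dc) in enumerate(offsets):
                    if patch[r + dr, c + dc] >= patch[r, c]:
                        code |= 1 << (7 - k)
                expected[code] += 1
        expected /= expected.sum()
        np.testing.assert_allclose(lbp_histogram(patch), expected, rtol=1e-12)


def test_lbp_too_small():
    with pytest.raises(PatchSizeError):
        lbp_histogram(np.zeros((2, 5)))


# ---------------------------------------------------------------- embeddings


def test_default_providers_deterministic_and_distinct(one_patch):
    a = deep_embed(one_patch, "C3", "p")
    b = deep_embed(one_patch, "C3", "p")
    assert a.dimension == 1024
    np.testing.assert_array_equal(a.values, b.values)
    zero = deep_embed(np.zeros((512, 512)), "GAP")
    bright = deep_embed(np.full((512, 512), 255.0), "GAP")
    assert not np.allclose(zero.values, bright.values)


def test_provider_dimension_contract_enforced():
    bad = SeededConvEmbedding("bad", seed=0, output_dim=1024)
    bad.output_dim = 999  # claims a dimension it does not produce
    with pytest.raises(EmbeddingContractError):
        deep_embed(np.zeros((64, 64)), bad)


def test_unknown_provider_name():
    with pytest.raises(KeyError, match="registered"):
        deep_embed(np.zeros((64, 64)), "resnet-please")


# --------------------------------------------------------------- aggregation


def test_aggregate_identity_and_mean():
    v = FeatureVector("p", "op", np.array([1.0, 2.0]))
    assert np.array_equal(aggregate_patches([v] * 15).values, v.values)
    pair = [
        FeatureVector("p", "op", np.array([0.0, 0.0])),
        FeatureVector("p", "op", np.array([2.0, 4.0])),
    ]
    assert np.array_equal(aggregate_patches(pair).values, [1.0, 2.0])


def test_aggregate_equals_direct_summation(rng):
    vs = [FeatureVector("p", "op", rng.normal(size=7)) for _ in range(9)]
    expected = sum(v.values for v in vs) / 9
    np.testing.assert_allclose(aggregate_patches(vs).values, expected, rtol=1e-12)


def test_aggregate_rejects_mixed_dimensions():
    with pytest.raises(ValueError, match="aggregate"):
        aggregate_patches(
            [FeatureVector("p", "op", np.zeros(3)), FeatureVector("p", "op", np.zeros(4))]
        )
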