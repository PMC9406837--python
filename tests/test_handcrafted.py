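"""Descriptor blocks against independent small-scale oracles."""

import numpy as np
import pytest
from skimage.color import hsv2rgb

from histofusion.handcrafted import (BLOCK_LAYOUT, TOTAL_FEATURES, dwt_features,
                                     fch_features, feature_names, glcm_features,
                                     glcm_matrix, handcrafted_features,
                                     haralick_stats, lbp_code, lbp_features,
                                     rgb_to_gray)


def haar_block_oracle(g):
    """Single-level orthonormal Haar as explicit 2x2 block sums/differences."""
    a = g[0::2, 0::2]
    b = g[0::2, 1::2]
    c = g[1::2, 0::2]
    d = g[1::2, 1::2]
    ll = (a + b + c + d) / 2
    lh = (a + b - c - d) / 2
    hl = (a - b + c - d) / 2
    hh = (a - b - c + d) / 2
    return ll, lh, hl, hh


class TestDWT:
    def test_constant_image(self):
        c = 50.0
        feats = dwt_features(np.full((8, 8), c))
        # details carry no energy; orthonormal Haar doubles the DC level
        assert np.allclose(feats[3:], 0.0)
        assert np.isclose(feats[0], 2 * c)
        assert np.allclose(feats[1:3], 0.0)

    def test_output_length_twelve(self, random_gray):
        assert dwt_features(random_gray(8, 8)).shape == (12,)

    def test_matches_block_transform_oracle(self, random_gray):
        g = random_gray(8, 8)
        bands = haar_block_oracle(g)
        feats = dwt_features(g)
        for i, band in enumerate(bands):
            assert np.isclose(feats[3 * i], band.mean(), atol=1e-9)
            assert np.isclose(feats[3 * i + 1], band.var(), atol=1e-9)
            assert np.isclose(feats[3 * i + 2], band.std(), atol=1e-9)

    def test_parseval_energy_preserved(self, rng):
        for _ in range(10):
            g = rng.uniform(0, 255, size=(2 * rng.integers(2, 10), 2 * rng.integers(2, 10)))
            ll, lh, hl, hh = haar_block_oracle(g)
            sub_energy = sum((band ** 2).sum() for band in (ll, lh, hl, hh))
            assert np.isclose(sub_energy, (g ** 2).sum(), rtol=1e-6)

    def test_odd_size_padded_not_rejected(self, random_gray):
        assert dwt_features(random_gray(7, 9)).shape == (12,)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            dwt_features(np.ones((1, 5)))


class TestLBP:
    def test_all_neighbors_equal_center_gives_all_ones(self):
        g = np.full((5, 5), 10.0)
        assert lbp_code(g, (2, 2)) == 2 ** 24 - 1  # s(0) = 1

    def test_all_neighbors_below_center_gives_zero(self):
        g = np.zeros((5, 5))
        g[2, 2] = 100.0
        assert lbp_code(g, (2, 2)) == 0

    def test_matches_direct_24_term_sum(self, random_gray):
        g = random_gray(5, 5)
        expected = 0
        p = 0
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                if (dr, dc) == (0, 0):
                    continue
                if g[2 + dr, 2 + dc] - g[2, 2] >= 0:
                    expected += 2 ** p
                p += 1
        assert lbp_code(g, (2, 2)) == expected

    def test_center_near_border_rejected(self):
        with pytest.raises(ValueError):
            lbp_code(np.zeros((7, 7)), (1, 3))

    def test_constant_image_histogram_one_hot_and_normalized(self):
        feats = lbp_features(np.full((9, 9), 5.0))
        assert feats.shape == (203,)
        assert np.isclose(feats.sum(), 1.0)
        # all-ones code lands in the final (remainder-absorbing) bin
        assert feats[202] == 1.0
        assert np.count_nonzero(feats) == 1

    def test_gray_shift_invariance(self, random_gray):
        g = random_gray(12, 12) * 0.5 + 20  # +10 will not clip
        assert np.allclose(lbp_features(g), lbp_features(g + 10.0))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            lbp_features(np.ones((4, 6)))


class TestFCH:
    def test_length_and_normalization(self, random_rgb):
        feats = fch_features(random_rgb(10, 10))
        assert feats.shape == (16,)
        assert np.isclose(feats.sum(), 1.0)

    def test_pure_color_on_bin_center(self):
        for j in (0, 3, 11):
            rgb = hsv2rgb(np.full((4, 4, 3), 1.0) * np.array([j / 16, 1.0, 0.8])) * 255
            feats = fch_features(rgb)
            assert np.isclose(feats[j], 1.0)

    def test_hue_midway_splits_mass_evenly(self):
        hue = (3 + 0.5) / 16
        rgb = hsv2rgb(np.full((4, 4, 3), 1.0) * np.array([hue, 1.0, 0.8])) * 255
        feats = fch_features(rgb)
        assert np.isclose(feats[3], 0.5, atol=1e-9)
        assert np.isclose(feats[4], 0.5, atol=1e-9)

    def test_achromatic_pixels_assigned_to_bin_zero(self):
        feats = fch_features(np.full((5, 5, 3), 128.0))
        assert feats[0] == 1.0

    def test_pixel_permutation_invariance(self, random_rgb, rng):
        img = random_rgb(8, 8)
        flat = img.reshape(-1, 3)
        perm = flat[rng.permutation(len(flat))].reshape(img.shape)
        assert np.allclose(fch_features(img), fch_features(perm))


def glcm_pair_oracle(gray, offset, levels):
    """From-scratch ordered-pair enumeration + symmetrize + normalize."""
    q = np.minimum((np.asarray(gray, float) * levels / 256.0).astype(int), levels - 1)
    dr, dc = offset
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    sym = counts + counts.T
    return sym / sym.sum()


class TestGLCM:
    def test_hand_enumerated_binary_example(self):
        # two columns of levels 0|1: two horizontal (0,1) pairs
        img = np.array([[0.0, 255.0], [0.0, 255.0]])
        P = glcm_matrix(img, theta=0, levels=2)
        assert np.allclose(P, [[0.0, 0.5], [0.5, 0.0]])
        stats = haralick_stats(P)
        assert np.isclose(stats[1], 1.0)   # contrast
        assert np.isclose(stats[0], 0.5)   # angular second moment

    def test_constant_image_statistics(self):
        P = glcm_matrix(np.full((6, 6), 90.0), theta=45)
        stats = haralick_stats(P)
        assert np.isclose(stats[0], 1.0)   # ASM: all mass in one cell
        assert np.isclose(stats[1], 0.0)   # contrast
        assert np.isclose(stats[8], 0.0)   # entropy

    def test_output_length_thirteen(self, random_gray):
        assert glcm_features(random_gray(8, 8)).shape == (13,)

    def test_matrix_properties(self, random_gray):
        for theta in (0, 45, 90, 135):
            P = glcm_matrix(random_gray(8, 8), theta)
            assert np.isclose(P.sum(), 1.0)
            assert np.allclose(P, P.T)

    def test_matches_pair_enumeration_oracle(self, rng):
        offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
        for _ in range(10):
            g = rng.uniform(0, 255, size=(8, 8))
            for theta, off in offsets.items():
                assert np.allclose(glcm_matrix(g, theta, levels=4),
                                   glcm_pair_oracle(g, off, 4), atol=1e-12)

    def test_haralick_stats_match_loop_definitions(self, rng):
        g = rng.uniform(0, 255, size=(8, 8))
        P = glcm_matrix(g, theta=0, levels=4)
        L = P.shape[0]
        asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
        contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
        entropy = -sum(P[i, j] * np.log(P[i, j])
                       for i in range(L) for j in range(L) if P[i, j] > 0)
        idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
        stats = haralick_stats(P)
        assert np.isclose(stats[0], asm)
        assert np.isclose(stats[1], contrast)
        assert np.isclose(stats[8], entropy)
        assert np.isclose(stats[4], idm)

    def test_image_too_small_for_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.ones((1, 3)), theta=90)


class TestConcatenation:
    def test_total_length_and_layout(self, random_rgb):
        fv = handcrafted_features(random_rgb(16, 16))
        assert fv.values.shape == (TOTAL_FEATURES,)
        assert sum(length for _, length in BLOCK_LAYOUT.values()) == TOTAL_FEATURES
        assert len(feature_names()) == TOTAL_FEATURES
        assert feature_names()[0] == "dwt_0" and feature_names()[-1] == "glcm_12"

    def test_constant_image_block_structure(self):
        fv = handcrafted_features(np.full((8, 8, 3), 120.0))
        lbp = fv.block("lbp")
        assert np.count_nonzero(lbp) == 1 and np.isclose(lbp.sum(), 1.0)
        assert np.isclose(fv.block("fch").sum(), 1.0)
        assert np.isclose(fv.block("glcm")[1], 0.0)  # contrast slot

    def test_deterministic(self, random_rgb):
        img = random_rgb(12, 12)
        assert np.array_equal(handcrafted_features(img).values,
                              handcrafted_features(img.copy()).values)

    def test_gray_conversion_weights(self):
        img = np.zeros((5, 5, 3))
        img[:, :, 1] = 100.0
        assert np.allclose(rgb_to_gray(img), 58.7)
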