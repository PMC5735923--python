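"""GLCM construction and the four texture statistics."""

import numpy as np
import pytest

from blastoquant import (
    EmptyRegionError,
    GLCMatrix,
    compute_glcm,
    glcm_contrast,
    glcm_correlation,
    glcm_energy,
    glcm_homogeneity,
    quantize8,
    texture_features,
)
from blastoquant.segment import EmbryoCircle, RegionMasks


def glcm_from_p(p):
    p = np.asarray(p, dtype=float)
    return GLCMatrix(p=p, d=1, theta=0.0, n_pairs=int(round(p.sum() * 100)) or 100)


def brute_force_glcm(q, mask, dr, dc, levels=8):
    """Independent O(n^2-ish) pair enumeration."""
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w and mask[i, j] and mask[i2, j2]:
                counts[q[i, j], q[i2, j2]] += 1
    n = counts.sum()
    return counts / n if n else counts, int(n)


def brute_force_stats(p):
    """Double-loop evaluation of the four statistics over the 8x8 grid."""
    contrast = energy = homog = 0.0
    mu_i = mu_j = 0.0
    for i in range(8):
        for j in range(8):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(8):
        for j in range(8):
            contrast += abs(i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    denom = np.sqrt(var_i) * np.sqrt(var_j)
    corr = cov / denom if denom > 0 else float("nan")
    return contrast, corr, energy, homog


class TestQuantize8:
    def test_constant_single_bin(self):
        q = quantize8(np.full((5, 5), 42), np.ones((5, 5), bool))
        assert (q == 0).all()

    def test_eight_even_values_span_levels(self):
        vals = np.array([[0, 36, 73, 109, 146, 182, 219, 255]])
        q = quantize8(vals, np.ones_like(vals, bool))
        assert q.tolist() == [[0, 1, 2, 3, 4, 5, 6, 7]]

    def test_single_pixel_mask(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        q = quantize8(np.arange(9).reshape(3, 3), mask)
        assert q[1, 1] == 0
        assert (q[~mask] == -1).all()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            quantize8(np.zeros((3, 3)), np.zeros((3, 3), bool))


class TestComputeGLCM:
    def test_constant_2x2(self):
        q = np.zeros((2, 2), dtype=int)
        g = compute_glcm(q, np.ones((2, 2), bool), d=1, theta=0.0)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0 and g.n_pairs == 2

    def test_alternating_row(self):
        q = np.array([[0, 7, 0, 7]])
        g = compute_glcm(q, np.ones((1, 4), bool), d=1, theta=0.0)
        assert g.n_pairs == 3
        assert g.p[0, 7] == pytest.approx(2 / 3)
        assert g.p[7, 0] == pytest.approx(1 / 3)

    def test_empty_mask_degenerate(self):
        g = compute_glcm(np.zeros((3, 3), int), np.zeros((3, 3), bool))
        assert g.degenerate and g.n_pairs == 0

    @pytest.mark.parametrize("theta,offset", [(0.0, (0, 1)), (45.0, (-1, 1)),
                                              (90.0, (-1, 0)), (135.0, (-1, -1))])
    def test_matches_pair_enumeration(self, rng, theta, offset):
        q = rng.integers(0, 8, (12, 15))
        mask = rng.random((12, 15)) > 0.25
        g = compute_glcm(q, mask, d=1, theta=theta)
        p_ref, n_ref = brute_force_glcm(q, mask, *offset)
        assert g.n_pairs == n_ref
        np.testing.assert_allclose(g.p, p_ref, atol=1e-15)


class TestStatistics:
    def test_constant_region_identities(self):
        q = np.zeros((6, 6), int)
        g = compute_glcm(q, np.ones((6, 6), bool))
        assert glcm_contrast(g) == 0.0
        assert glcm_energy(g) == 1.0
        assert glcm_homogeneity(g) == 1.0
        assert np.isnan(glcm_correlation(g))  # zero variance: undefined

    def test_antidiagonal_pair_values(self):
        p = np.zeros((8, 8))
        p[0, 7] = p[7, 0] = 0.5
        g = glcm_from_p(p)
        assert glcm_contrast(g) == pytest.approx(49.0)
        assert glcm_correlation(g) == pytest.approx(-1.0)
        assert glcm_energy(g) == pytest.approx(0.5)
        assert glcm_homogeneity(g) == pytest.approx(0.125)

    def test_uniform_glcm_energy(self):
        g = glcm_from_p(np.full((8, 8), 1 / 64))
        assert glcm_energy(g) == pytest.approx(1 / 64)

    def test_shifted_diagonal_correlation_is_one(self):
        # neighbour pairs exactly on j = i + 1 across several levels
        row = np.array([0, 36, 73, 109, 146, 182, 219, 255])
        img = np.tile(row, (10, 1))
        mask = np.ones_like(img, bool)
        q = quantize8(img, mask)
        g = compute_glcm(q, mask)
        assert glcm_correlation(g) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_brute_force_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (20, 20))
        mask = rng.random((20, 20)) > 0.2
        q = quantize8(img, mask)
        g = compute_glcm(q, mask)
        c_ref, r_ref, e_ref, h_ref = brute_force_stats(g.p)
        assert glcm_contrast(g) == pytest.approx(c_ref, abs=1e-12)
        assert glcm_correlation(g) == pytest.approx(r_ref, abs=1e-12)
        assert glcm_energy(g) == pytest.approx(e_ref, abs=1e-12)
        assert glcm_homogeneity(g) == pytest.approx(h_ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_bounds_and_intensity_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        # odd values keep quantization off exact bin edges under the flip
        img = rng.integers(0, 128, (25, 25)) * 2 + 1
        mask = rng.random((25, 25)) > 0.3
        q = compute_glcm(quantize8(img, mask), mask)
        assert glcm_contrast(q) >= 0
        assert 0 < glcm_energy(q) <= 1
        assert 0 < glcm_homogeneity(q) <= 1
        assert abs(glcm_correlation(q)) <= 1 + 1e-12
        flipped = compute_glcm(quantize8(255 - img, mask), mask)
        assert glcm_contrast(flipped) == pytest.approx(glcm_contrast(q), abs=1e-12)
        assert glcm_energy(flipped) == pytest.approx(glcm_energy(q), abs=1e-12)
        assert glcm_homogeneity(flipped) == pytest.approx(glcm_homogeneity(q), abs=1e-12)

    def test_matches_skimage_on_unmasked_rectangle(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        q = rng.integers(0, 8, (30, 30)).astype(np.uint8)
        g = compute_glcm(q, np.ones_like(q, bool))
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=False, normed=True)
        np.testing.assert_allclose(g.p, ref[:, :, 0, 0], atol=1e-12)
        assert glcm_contrast(g) == pytest.approx(graycoprops(ref, "contrast")[0, 0])
        assert glcm_energy(g) == pytest.approx(graycoprops(ref, "ASM")[0, 0])
        assert glcm_correlation(g) == pytest.approx(graycoprops(ref, "correlation")[0, 0])
        # no homogeneity cross-check: the library's variant divides by
        # 1 + (i-j)^2 rather than 1 + |i-j|


def synthetic_masks(crop, rr, te):
    """Hand-built RegionMasks carrier for texture tests."""
    h, w = crop.shape
    er = rr | te
    return RegionMasks(
        circle=EmbryoCircle(w / 2, h / 2, 100.0, 1.0, 1),
        er_mask=er, rr_mask=rr, te_mask=te,
        crop=crop, crop_er_mask=er, crop_rr_mask=rr, crop_te_mask=te,
        crop_origin=(0, 0), total_area=int(er.sum()), radius_er=105.0,
    )


class TestTextureFeatures:
    def test_constant_rr_interior(self, rng):
        crop = rng.integers(0, 256, (60, 60)).astype(np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        rr = np.hypot(xx - 30, yy - 30) <= 12
        crop[rr] = 99
        te = (np.hypot(xx - 30, yy - 30) <= 25) & ~rr
        vals, flags = texture_features(synthetic_masks(crop, rr, te))
        assert vals["Energy RR"] == 1.0 and vals["Contrast RR"] == 0.0
        assert "correlation_undefined_rr" in flags
        assert np.isnan(vals["Correlation RR"])

    def test_identical_regions_give_identical_statistics(self, rng):
        crop = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        disc = np.hypot(xx - 20, yy - 20) <= 15
        vals, _ = texture_features(synthetic_masks(crop, disc, disc.copy()))
        for name in ("Contrast", "Correlation", "Energy", "Homogeneity"):
            assert vals[f"{name} RR"] == pytest.approx(vals[f"{name} TE"], abs=1e-9)

    def test_phantom_values_finite_and_bounded(self, inclusion_phantom):
        vals, _ = texture_features(inclusion_phantom["masks"])
        assert len(vals) == 8
        for suffix in ("RR", "TE"):
            assert vals[f"Contrast {suffix}"] >= 0
            assert 0 < vals[f"Energy {suffix}"] <= 1
            assert 0 < vals[f"Homogeneity {suffix}"] <= 1
            assert abs(vals[f"Correlation {suffix}"]) <= 1
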