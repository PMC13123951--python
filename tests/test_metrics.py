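import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from usgan.metrics import (GLCMatrix, ROIPair, RandomConvFeatures, auto_roi,
                           compute_report, contrast_ratio, contrast_to_noise,
                           evaluate_set, fid_score, first_order_stats,
                           frechet_distance, glcm, glcm_features,
                           patchwise_ssim)
from usgan.images import save_image

RNG = np.random.default_rng(31)


# ---------------------------------------------------------------------------
# brute-force oracles (pure-python, independent of the implementation)


def oracle_glcm_features(img, levels, offset, symmetric):
    h, w = img.shape
    q = [[min(int(img[r][c] * levels), levels - 1) for c in range(w)]
         for r in range(h)]
    dr, dc = offset
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs.append((q[r][c], q[r2][c2]))
                if symmetric:
                    pairs.append((q[r2][c2], q[r][c]))
    total = len(pairs)
    p = {}
    for ij in pairs:
        p[ij] = p.get(ij, 0) + 1 / total
    contrast = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    energy = sum(v * v for v in p.values())
    homo = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    mu_i = sum(v * i for (i, j), v in p.items())
    mu_j = sum(v * j for (i, j), v in p.items())
    si = math.sqrt(sum(v * (i - mu_i) ** 2 for (i, j), v in p.items()))
    sj = math.sqrt(sum(v * (j - mu_j) ** 2 for (i, j), v in p.items()))
    if si * sj == 0:
        corr = 1.0
    else:
        corr = sum(v * (i - mu_i) * (j - mu_j) for (i, j), v in p.items()) / (si * sj)
    return contrast, corr, energy, homo


def oracle_ssim(a, b):
    a, b = [x.ravel().tolist() for x in (a, b)]
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    va = sum((x - ma) ** 2 for x in a) / (n - 1)
    vb = sum((x - mb) ** 2 for x in b) / (n - 1)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / (n - 1)
    c1, c2 = 0.01**2, 0.03**2
    return ((2 * ma * mb + c1) * (2 * cov + c2)
            / ((ma**2 + mb**2 + c1) * (va + vb + c2)))


def oracle_first_order(img):
    v = img.ravel().tolist()
    n = len(v)
    mu = sum(v) / n
    var = sum((x - mu) ** 2 for x in v) / n
    sd = math.sqrt(var)
    skew = 0.0 if sd == 0 else sum((x - mu) ** 3 for x in v) / n / sd**3
    counts = {}
    for x in v:
        b = min(int(x * 256), 255)
        counts[b] = counts.get(b, 0) + 1
    ent = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return mu, sd, skew, ent


# ---------------------------------------------------------------------------


class TestContrastMetrics:
    def test_cr_hand_arithmetic_and_symmetry(self):
        img = np.array([[200, 100], [200, 100]]) / 255.0
        roi = ROIPair(np.array([[1, 0], [1, 0]], bool),
                      np.array([[0, 1], [0, 1]], bool))
        swapped = ROIPair(roi.bg_mask, roi.fg_mask)
        assert contrast_ratio(img, roi) == pytest.approx(100.0)
        assert contrast_ratio(img, swapped) == contrast_ratio(img, roi)
        assert contrast_ratio(np.full((2, 2), 0.5), roi) == 0.0

    def test_cnr_hand_arithmetic_and_scale_invariance(self):
        img = np.array([[90, 110, 40, 60]]) / 255.0
        roi = ROIPair(np.array([[1, 1, 0, 0]], bool),
                      np.array([[0, 0, 1, 1]], bool))
        assert contrast_to_noise(img, roi) == pytest.approx(3.5355339, abs=1e-6)
        assert contrast_to_noise(img * 0.37, roi) == pytest.approx(
            contrast_to_noise(img, roi))

    def test_cnr_undefined_for_flat_regions(self):
        from usgan.metrics import ROIError
        roi = ROIPair(np.array([[1, 1, 0, 0]], bool),
                      np.array([[0, 0, 1, 1]], bool))
        with pytest.raises(ROIError, match="undefined"):
            contrast_to_noise(np.full((1, 4), 0.4), roi)

    def test_cr_cnr_match_mask_indexed_oracle_on_random_inputs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            img = rng.uniform(0, 1, (8, 8))
            fg = np.zeros((8, 8), bool)
            bg = np.zeros((8, 8), bool)
            fg[:4], bg[4:] = rng.uniform(0, 1, (4, 8)) < 0.6, rng.uniform(0, 1, (4, 8)) < 0.6
            if not fg.any() or not bg.any():
                continue
            roi = ROIPair(fg, bg)
            f = [img[r][c] for r in range(8) for c in range(8) if fg[r][c]]
            b = [img[r][c] for r in range(8) for c in range(8) if bg[r][c]]
            mf, mb = sum(f) / len(f), sum(b) / len(b)
            assert contrast_ratio(img, roi) == pytest.approx(abs(mf - mb) * 255)
            vf = sum((x - mf) ** 2 for x in f) / len(f)
            vb = sum((x - mb) ** 2 for x in b) / len(b)
            if len(f) > 1 and len(b) > 1 and vf + vb > 0:
                assert contrast_to_noise(img, roi) == pytest.approx(
                    abs(mf - mb) / math.sqrt(vf + vb))

    def test_roi_validation(self):
        from usgan.metrics import ROIError
        with pytest.raises(ROIError):
            ROIPair(np.ones((2, 2), bool), np.ones((2, 2), bool))  # overlap
        with pytest.raises(ROIError):
            ROIPair(np.zeros((2, 2), bool), np.ones((2, 2), bool))  # empty


class TestPatchwiseSSIM:
    def test_identity_is_exactly_one(self):
        img = RNG.uniform(0, 1, (32, 32))
        assert patchwise_ssim(img, img, patch=16, stride=8) == 1.0

    def test_anticorrelated_binary_is_negative(self):
        img = (RNG.uniform(0, 1, (16, 16)) > 0.5).astype(float)
        assert patchwise_ssim(img, 1.0 - img, patch=8, stride=8) < 0.0

    def test_matches_brute_force_oracle(self):
        a = RNG.uniform(0, 1, (16, 16))
        b = np.clip(a + RNG.normal(0, 0.2, (16, 16)), 0, 1)
        mine = patchwise_ssim(a, b, patch=8, stride=8)
        oracle = np.mean([oracle_ssim(a[r:r + 8, c:c + 8], b[r:r + 8, c:c + 8])
                          for r in (0, 8) for c in (0, 8)])
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_whole_image_patch_equals_global_ssim(self):
        from skimage.metrics import structural_similarity
        a = RNG.uniform(0, 1, (15, 15))
        b = np.clip(a + RNG.normal(0, 0.1, (15, 15)), 0, 1)
        mine = patchwise_ssim(a, b, patch=15)
        sk = structural_similarity(a, b, win_size=15, data_range=1.0,
                                   gaussian_weights=False)
        assert mine == pytest.approx(sk, abs=1e-12)

    def test_luminance_shift_changes_score_only_mildly(self):
        a = RNG.uniform(0.1, 0.5, (16, 16))
        b = np.clip(a + RNG.normal(0, 0.05, (16, 16)), 0, 0.6)
        base = patchwise_ssim(a, b, patch=16)
        shifted = patchwise_ssim(a + 0.3, b + 0.3, patch=16)
        assert abs(base - shifted) < 0.02

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            patchwise_ssim(np.zeros((8, 8)), np.zeros((9, 9)), patch=4)


class TestFirstOrderStats:
    def test_constant_image_degenerate_conventions(self):
        mu, sd, skew, ent = first_order_stats(np.full((8, 8), 0.42))
        assert sd == 0.0 and skew == 0.0 and ent == 0.0
        assert mu == pytest.approx(0.42)

    def test_entropy_of_uniform_256_levels_is_8_bits(self):
        img = (np.arange(256) / 255.0).reshape(16, 16)
        assert first_order_stats(img)[3] == pytest.approx(8.0)

    def test_symmetric_two_level_image_has_zero_skewness(self):
        img = np.array([[0.2, 0.8]] * 8)
        assert first_order_stats(img)[2] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        img = RNG.uniform(0, 1, (16, 16))
        mine = first_order_stats(img)
        oracle = oracle_first_order(img)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)


class TestGLCM:
    def test_two_row_example(self):
        g = glcm(np.array([[0.0, 0.0], [0.9, 0.9]]), levels=2, offset=(0, 1),
                 symmetric=True)
        assert g.counts[0, 0] == pytest.approx(0.5)
        assert g.counts[1, 1] == pytest.approx(0.5)
        contrast, corr, energy, homo = glcm_features(g)
        assert (contrast, corr, energy, homo) == pytest.approx((0, 1, 0.5, 1))

    def test_checkerboard_features(self):
        board = np.indices((8, 8)).sum(0) % 2 * 0.9
        g = glcm(board, levels=2, offset=(0, 1), symmetric=True)
        contrast, corr, energy, homo = glcm_features(g)
        assert contrast == pytest.approx(1.0)
        assert homo == pytest.approx(0.5)
        assert corr == pytest.approx(-1.0)

    def test_constant_image_single_entry(self):
        g = glcm(np.full((4, 4), 0.5), levels=4, offset=(0, 1))
        assert g.counts.sum() == pytest.approx(1.0)
        assert np.count_nonzero(g.counts) == 1
        assert glcm_features(g)[1] == 1.0  # correlation convention

    def test_normalization_for_any_input(self):
        for seed in range(4):
            img = np.random.default_rng(seed).uniform(0, 1, (8, 8))
            assert glcm(img, levels=6, offset=(1, -1)).counts.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (0, 2)])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_features_match_brute_force_enumeration(self, offset, symmetric):
        for seed in range(3):
            img = np.random.default_rng(seed).uniform(0, 1, (8, 8))
            mine = glcm_features(glcm(img, 4, offset, symmetric))
            oracle = oracle_glcm_features(img, 4, offset, symmetric)
            np.testing.assert_allclose(mine, oracle, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(np.float64, (8, 8),
                      elements=st.floats(0, 1, allow_nan=False)),
           st.integers(2, 8))
    def test_glcm_invariants_hold_for_any_image(self, img, levels):
        g = glcm(img, levels=levels, offset=(0, 1), symmetric=True)
        contrast, corr, energy, homo = glcm_features(g)
        assert g.counts.sum() == pytest.approx(1.0)
        assert np.all(g.counts >= 0)
        assert 0 < energy <= 1 + 1e-12
        assert 0 < homo <= 1 + 1e-12
        assert contrast >= 0
        assert -1 - 1e-9 <= corr <= 1 + 1e-9

    def test_uniform_matrix_energy(self):
        g = GLCMatrix(np.ones((4, 4)), 4, (0, 1), True)
        assert glcm_features(g)[2] == pytest.approx(1 / 16)

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            glcm(np.zeros((4, 4)), levels=2, offset=(0, 4))


class TestFrechet:
    def test_identical_sets_are_zero(self):
        feats = RNG.normal(size=(40, 5))
        assert frechet_distance(feats, feats.copy()) < 1e-6

    def test_one_dimensional_closed_form(self):
        # population moments exact: A has mu=0, sigma=1; B has mu=1, sigma=1
        a = np.array([[-1.0], [1.0]])
        b = np.array([[0.0], [2.0]])
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-6)
        # sigma difference term: B' has mu=0, sigma=2
        b2 = np.array([[-2.0], [2.0]])
        assert frechet_distance(a, b2) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self):
        a = RNG.normal(size=(30, 3))
        b = RNG.normal(loc=0.5, size=(25, 3))
        assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a),
                                                       rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(np.zeros((3, 2)), np.zeros((3, 4)))


class TestFID:
    def test_identical_sets_zero(self):
        imgs = [RNG.uniform(0, 1, (64, 64)) for _ in range(4)]
        assert fid_score(imgs, [im.copy() for im in imgs]) < 1e-6

    def test_disjoint_constant_sets_positive(self):
        a = [np.full((64, 64), 0.2) + 0.001 * i for i in range(3)]
        b = [np.full((64, 64), 0.8) - 0.001 * i for i in range(3)]
        assert fid_score(a, b) > 0.0

    def test_order_invariance(self):
        ex = RandomConvFeatures(seed=3)
        a = [RNG.uniform(0, 1, (64, 64)) for _ in range(4)]
        b = [RNG.uniform(0, 1, (64, 64)) for _ in range(4)]
        assert fid_score(a, b, ex) == pytest.approx(
            fid_score(a[::-1], b, ex), rel=1e-6)


class TestEvaluateSet:
    def test_report_rows_and_mean(self, tmp_path):
        d = tmp_path / "imgs"
        d.mkdir()
        for i in range(3):
            save_image(np.random.default_rng(i).uniform(0, 1, (64, 64)),
                       d / f"im_{i}.png")
        df = evaluate_set(d, out_csv=tmp_path / "report.csv",
                          allow_auto_roi=True)
        assert len(df) == 4 and df.iloc[-1]["file"] == "mean"
        assert (tmp_path / "report.csv").exists()
        assert np.isfinite(df["cr"].iloc[:-1]).all()

    def test_self_reference_gives_unit_ssim(self, tmp_path):
        d = tmp_path / "imgs"
        d.mkdir()
        save_image(np.random.default_rng(0).uniform(0, 1, (64, 64)),
                   d / "a.png")
        df = evaluate_set(d, ref_dir=d, allow_auto_roi=True)
        assert df["patch_ssim"].iloc[0] == pytest.approx(1.0)

    def test_missing_masks_raise_without_fallback(self, tmp_path):
        from usgan.metrics import ROIError
        d = tmp_path / "imgs"
        masks = tmp_path / "masks"
        d.mkdir()
        masks.mkdir()
        save_image(np.zeros((32, 32)), d / "a.png")
        with pytest.raises(ROIError, match="mask"):
            evaluate_set(d, roi_source=masks)

    def test_domain_separation_on_phantom_set(self, phantom_dataset):
        root = phantom_dataset["root"]
        df_x = evaluate_set(root / "X", roi_source=root / "masks")
        df_y = evaluate_set(root / "Y", roi_source=root / "masks")
        assert df_x["cr"].iloc[-1] < df_y["cr"].iloc[-1]

    def test_compute_report_auto_roi_shape(self):
        rep = compute_report(RNG.uniform(0, 1, (64, 64)),
                             roi=auto_roi((64, 64)))
        assert np.isfinite(rep.cr) and np.isfinite(rep.glcm_energy)
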