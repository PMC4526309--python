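import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texnac.texture import (
    GLCM_FEATURES,
    QuantizedImage,
    glcm,
    glcm_features,
    quantize,
    rlm,
    rlm_features,
    texture_map,
)

from .conftest import random_masked_image
from .oracles import (
    glcm_bruteforce,
    glcm_features_literal,
    rlm_bruteforce,
    rlm_features_literal,
)


def qimg(levels, mask=None, n_levels=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    if n_levels is None:
        n_levels = int(levels.max()) + 1
    return QuantizedImage(levels, n_levels, np.asarray(mask, dtype=bool))


class TestQuantize:
    def test_five_bit_linear_binning(self):
        """Values 0..255 at 5 bits bin as floor(value / 8)."""
        img = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(img, np.ones((16, 16), dtype=bool), bits=5)
        assert q.n_levels == 32
        assert np.array_equal(q.levels, np.floor(img / 8).astype(int))

    def test_constant_image_all_level_zero(self):
        q = quantize(np.full((4, 4), 7.0), np.ones((4, 4), dtype=bool))
        assert np.all(q.levels == 0)

    def test_max_maps_to_top_level(self, rng):
        img = rng.normal(size=(10, 10))
        q = quantize(img, np.ones((10, 10), dtype=bool), bits=3)
        assert q.levels.max() == 7 and q.levels.min() == 0

    @settings(deadline=None, max_examples=25)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0), seed=st.integers(0, 10**6))
    def test_affine_intensity_invariance(self, a, b, seed):
        """Quantization is unchanged under x -> a*x + b with a > 0."""
        r = np.random.default_rng(seed)
        img = r.normal(0, 10, size=(9, 9))
        mask = r.random((9, 9)) < 0.8
        mask[4, 4] = True
        q1 = quantize(img, mask, bits=4)
        q2 = quantize(a * img + b, mask, bits=4)
        assert np.array_equal(q1.levels[mask], q2.levels[mask])


class TestGlcm:
    def test_two_by_two_hand_enumeration(self):
        """[[0,0],[1,1]]: 12 ordered pairs — 4 horizontal (equal levels),
        4 vertical and 2 per diagonal (mixed) — so p(0,1) = p(1,0) = 4/12."""
        m = glcm(qimg([[0, 0], [1, 1]]))
        assert m.p[0, 1] == pytest.approx(1 / 3)
        assert m.p[1, 0] == pytest.approx(1 / 3)
        assert m.p[0, 0] == pytest.approx(1 / 6)
        assert m.p.sum() == pytest.approx(1.0)
        expected = glcm_bruteforce(np.array([[0, 0], [1, 1]]), np.ones((2, 2), bool), 2)
        assert np.allclose(m.p, expected)

    def test_constant_image_single_cell(self):
        m = glcm(qimg(np.zeros((3, 3), dtype=int), n_levels=4))
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_masked_images(self, rng):
        for _ in range(200):
            levels, mask = random_masked_image(rng)
            try:
                m = glcm(qimg(levels * mask, mask, n_levels=8))
            except ValueError:
                continue  # no valid pair: oracle would reject too
            expected = glcm_bruteforce(levels * mask, mask, 8)
            assert np.allclose(m.p, expected, atol=1e-14)

    def test_single_isolated_pixel_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(ValueError, match="no valid pixel pair"):
            glcm(qimg(np.zeros((3, 3), dtype=int), mask, n_levels=2))

    def test_symmetry_and_rotation_invariance(self, rng):
        """Pooled 4-direction GLCM is invariant to transpose and 180-deg rotation."""
        levels, mask = random_masked_image(rng, min_side=10, max_side=10)
        p0 = glcm(qimg(levels * mask, mask, n_levels=8)).p
        assert np.allclose(p0, p0.T)
        pt = glcm(qimg((levels * mask).T, mask.T, n_levels=8)).p
        p180 = glcm(qimg(np.rot90(levels * mask, 2), np.rot90(mask, 2), n_levels=8)).p
        assert np.allclose(p0, pt)
        assert np.allclose(p0, p180)


class TestGlcmFeatures:
    def test_constant_image_degenerate_limits(self):
        with pytest.warns(UserWarning, match="correlation set to 0"):
            f = glcm_features(glcm(qimg(np.zeros((4, 4), dtype=int), n_levels=32)))
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["inv_diff_moment"] == pytest.approx(1.0)

    def test_checkerboard_matches_bruteforce(self):
        levels = np.indices((6, 6)).sum(axis=0) % 2
        m = glcm(qimg(levels, n_levels=2))
        f = glcm_features(m)
        ref = glcm_features_literal(glcm_bruteforce(levels, np.ones((6, 6), bool), 2))
        for k in GLCM_FEATURES:
            assert f[k] == pytest.approx(ref[k], abs=1e-10), k

    def test_matches_literal_formula_oracle(self, rng):
        for _ in range(50):
            levels, mask = random_masked_image(rng)
            try:
                m = glcm(qimg(levels * mask, mask, n_levels=8))
            except ValueError:
                continue
            f = glcm_features(m)
            ref = glcm_features_literal(m.p)
            for k in GLCM_FEATURES:
                assert f[k] == pytest.approx(ref[k], abs=1e-10), k

    def test_energy_one_iff_entropy_zero(self, rng):
        for _ in range(30):
            levels, mask = random_masked_image(rng, min_side=4, max_side=8, n_levels=3)
            try:
                f = glcm_features(glcm(qimg(levels * mask, mask, n_levels=3)))
            except ValueError:
                continue
            assert (f["energy"] == pytest.approx(1.0)) == (f["entropy"] == pytest.approx(0.0, abs=1e-12))


class TestRlm:
    def test_single_row_hand_enumeration(self):
        """[0,0,0,1,1,2] horizontally: runs of length 3, 2 and 1."""
        levels = np.array([[0, 0, 0, 1, 1, 2]])
        r = rlm(qimg(levels, n_levels=3), directions=((0, 1),))
        assert r.n_runs == 3
        assert r.r[0, 2] == 1 and r.r[1, 1] == 1 and r.r[2, 0] == 1
        assert r.pixel_basis == 6

    def test_constant_square_single_direction(self):
        n = 5
        r = rlm(qimg(np.zeros((n, n), dtype=int), n_levels=2), directions=((0, 1),))
        assert r.n_runs == n
        assert r.r[0, n - 1] == n

    def test_run_lengths_partition_pixels(self, rng):
        """Sum of j * r(i, j) equals the in-mask pixel count per direction."""
        for direction in ((0, 1), (-1, 0), (-1, 1), (-1, -1)):
            levels, mask = random_masked_image(rng)
            r = rlm(qimg(levels * mask, mask, n_levels=8), directions=(direction,))
            j = np.arange(1, r.r.shape[1] + 1)
            assert (r.r * j).sum() == mask.sum()

    def test_matches_bruteforce_on_random_masked_images(self, rng):
        for _ in range(200):
            levels, mask = random_masked_image(rng)
            r = rlm(qimg(levels * mask, mask, n_levels=8))
            ref_r, ref_runs, ref_basis = rlm_bruteforce(levels * mask, mask, 8)
            assert np.array_equal(r.r, ref_r)
            assert r.n_runs == ref_runs
            assert r.pixel_basis == ref_basis

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            rlm(qimg(np.zeros((3, 3), dtype=int), np.zeros((3, 3), bool), n_levels=2))


class TestRlmFeatures:
    def test_single_row_hand_computation(self):
        levels = np.array([[0, 0, 0, 1, 1, 2]])
        r = rlm(qimg(levels, n_levels=3), directions=((0, 1),))
        f = rlm_features(r)
        assert f["sre"] == pytest.approx((1 / 9 + 1 / 4 + 1) / 3)
        assert f["lre"] == pytest.approx((9 + 4 + 1) / 3)
        assert f["rp"] == pytest.approx(0.5)
        assert f["gln"] == pytest.approx(1.0)

    def test_constant_square_closed_form(self):
        n = 6
        r = rlm(qimg(np.zeros((n, n), dtype=int), n_levels=2), directions=((0, 1),))
        f = rlm_features(r)
        assert f["lre"] == pytest.approx(n ** 2)
        assert f["sre"] == pytest.approx(1 / n ** 2)
        assert f["gln"] == pytest.approx(n)

    def test_matches_literal_formula_oracle(self, rng):
        for _ in range(50):
            levels, mask = random_masked_image(rng)
            r = rlm(qimg(levels * mask, mask, n_levels=8))
            f = rlm_features(r)
            ref = rlm_features_literal(r.r, r.n_runs, r.pixel_basis)
            for k in ref:
                assert f[k] == pytest.approx(ref[k], abs=1e-10), k


class TestTextureMap:
    def test_flat_image_flagged_zero_map(self):
        with pytest.warns(UserWarning, match="flat feature map"):
            out = texture_map(np.full((5, 5), 3.0), "contrast")
        assert np.all(out == 0.0)

    def test_interior_pixel_matches_crop_features(self, rng):
        img = rng.normal(0, 10, size=(7, 7))
        raw = texture_map(img, "homogeneity", scaled=False)
        crop = img[2:5, 2:5]
        q = quantize(crop, np.ones((3, 3), dtype=bool), bits=5)
        assert raw[3, 3] == pytest.approx(glcm_features(glcm(q))["homogeneity"])

    def test_scaled_range_0_255(self, rng):
        img = rng.normal(0, 10, size=(6, 6))
        out = texture_map(img, "entropy")
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(255.0)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window larger"):
            texture_map(np.zeros((2, 2)), "contrast", window=3)

    def test_smooth_region_more_homogeneous_than_textured(self, rng):
        img = np.zeros((12, 24))
        img[:, 12:] = rng.normal(0, 20, size=(12, 12))  # textured right half
        img[:, :12] = np.linspace(0, 5, 12)[None, :]  # smooth left half
        raw = texture_map(img, "homogeneity", scaled=False)
        assert raw[:, 2:10].mean() > raw[:, 14:22].mean()


class TestHeterogeneityDirection:
    def test_correlation_length_drives_homogeneity(self):
        """Smoother lesions (longer field correlation) score higher homogeneity
        and inverse difference moment, lower entropy — the non-responder
        texture direction the cohort generator plants."""
        from texnac import PhantomConfig, generate_phantom
        from texnac.pipeline import extract_patient_features

        means = {}
        for cl in (0.5, 1.5, 3.0):
            feats = []
            for seed in range(10):
                cfg = PhantomConfig(lesion_texture_corr_len=cl, noise_sd=1.0, seed=seed)
                series, truth = generate_phantom(cfg)
                feats.append(extract_patient_features(series, truth.lesion_mask))
            means[cl] = {k: np.mean([f[k] for f in feats])
                         for k in ("homogeneity", "inv_diff_moment", "entropy")}
        assert means[0.5]["homogeneity"] < means[1.5]["homogeneity"] < means[3.0]["homogeneity"]
        assert means[0.5]["inv_diff_moment"] < means[1.5]["inv_diff_moment"] < means[3.0]["inv_diff_moment"]
        assert means[0.5]["entropy"] > means[1.5]["entropy"] > means[3.0]["entropy"]
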