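import dataclasses

import numpy as np
import pytest

import fovalign as fa
from fovalign.alignment import extract_pooled_features


class TestApplyTransform:
    def test_identity_returns_input(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (40, 40)).astype(np.uint8)
        out = fa.apply_transform(fa.AffineTransform2D.identity(), img, "nearest")
        assert np.array_equal(out, img)

    def test_pure_translation_moves_pixel(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[15, 10] = 255
        t = fa.AffineTransform2D(e=10.0, f=0.0)
        out = fa.apply_transform(t, mask, "nearest")
        assert out[15, 20] == 255
        assert out.sum() == 255

    def test_nearest_keeps_values_binary(self, session_pair):
        moving, template, true = session_pair
        out = fa.apply_transform(true, moving.mask.image, "nearest",
                                 output_shape=template.mask.image.shape)
        assert set(np.unique(out)) <= {0, 255}

    def test_mask_round_trip_recovers_95_percent(self, small_scene):
        r = fa.render_session(small_scene, seed=0)
        t = fa.AffineTransform2D(a=1.02, b=0.1, c=-0.08, d=0.97, e=5.0, f=-3.0)
        there = fa.apply_transform(t, r.mask.image, "nearest")
        back = fa.apply_transform(t.inverse(), there, "nearest")
        fg = r.mask.image == 255
        assert (back[fg] == 255).mean() >= 0.95

    def test_singular_transform_rejected(self):
        t = fa.AffineTransform2D(a=0.0, d=0.0)
        with pytest.raises(ValueError):
            fa.apply_transform(t, np.zeros((8, 8)))


class TestL1MaskScore:
    def test_identical_masks_score_zero(self, small_scene):
        m = fa.render_session(small_scene, seed=0).mask.image
        assert fa.l1_mask_score(fa.AffineTransform2D.identity(), m, m) == 0.0

    def test_disjoint_masks_score_symmetric_difference(self):
        a = np.zeros((50, 50), np.uint8)
        b = np.zeros((50, 50), np.uint8)
        a[:10, :10] = 255   # 100 foreground px
        b[30:38, 30:40] = 255  # 80 foreground px
        score = fa.l1_mask_score(fa.AffineTransform2D.identity(), a, b)
        assert score == 255 * 180

    def test_true_transform_beats_identity(self, session_pair):
        moving, template, true = session_pair
        s_true = fa.l1_mask_score(true, moving.mask.image, template.mask.image)
        s_id = fa.l1_mask_score(fa.AffineTransform2D.identity(),
                                moving.mask.image, template.mask.image)
        assert s_true < s_id


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 120, np.uint8)
        out = fa.clahe_preprocess(img)
        assert len(np.unique(out)) == 1

    def test_output_range_contract(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (100, 130)).astype(np.uint8)
        out = fa.clahe_preprocess(img)
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255

    def test_enhances_low_contrast_fov(self, blob_image):
        img, _ = blob_image
        squeezed = (img.astype(float) / 255.0 * 30 + 100).astype(np.uint8)
        out = fa.clahe_preprocess(squeezed)
        assert out.std() > squeezed.std()

    def test_requires_8bit(self):
        with pytest.raises(ValueError):
            fa.clahe_preprocess(np.zeros((32, 32), np.uint16))


class TestPooledFeatures:
    def test_pose_index_zero_is_frontal_subset(self, blob_image):
        img, _ = blob_image
        pooled = extract_pooled_features(img, "brief", max_tilt_index=1)
        frontal = fa.detect_and_describe(img, "brief")
        sub = pooled.take(pooled.source_pose_index == 0)
        assert len(sub) <= len(frontal)
        assert len(sub) > 0

    def test_pooling_adds_features(self, blob_image):
        img, _ = blob_image
        pooled = extract_pooled_features(img, "brief", max_tilt_index=2)
        frontal = fa.detect_and_describe(img, "brief")
        assert len(pooled) > len(frontal)


def _strip_arrays(result):
    return dataclasses.asdict(
        result, dict_factory=lambda kv: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                         for k, v in kv})


class TestAlignFov:
    def test_self_alignment_is_identity_with_zero_l1(self, session_pair):
        moving, _, _ = session_pair
        res = fa.align_fov(moving.image, moving.image, moving.mask.image,
                           moving.mask.image, backend_name="brief",
                           n_repeats=5, seed=0, max_tilt_index=1,
                           ransac_iterations=2000)
        err = res.transform.corner_displacement(
            fa.AffineTransform2D.identity(), moving.image.shape)
        assert err < 0.5
        assert min(res.l1_scores) == 0.0

    def test_recovers_known_session_transform(self, session_pair):
        moving, template, true = session_pair
        res = fa.align_fov(moving.image, template.image, moving.mask.image,
                           template.mask.image, backend_name="sift",
                           n_repeats=10, seed=1, max_tilt_index=2,
                           ransac_iterations=5000)
        assert res.transform.corner_displacement(true, moving.image.shape) < 2.0
        warped = fa.apply_transform(res.transform, moving.mask.image, "nearest",
                                    output_shape=template.mask.image.shape)
        shared = set(moving.visible_ids) & set(template.visible_ids)
        assert len(shared) > 0
        assert fa.mask_correlation(warped, template.mask.image) > 0.5

    def test_selection_is_argmin_of_l1(self, session_pair):
        moving, template, _ = session_pair
        res = fa.align_fov(moving.image, template.image, moving.mask.image,
                           template.mask.image, backend_name="orb",
                           n_repeats=8, seed=2, max_tilt_index=1,
                           ransac_iterations=3000)
        assert res.l1_scores[res.selected_repeat] == min(res.l1_scores)
        assert res.inlier_ratio == pytest.approx(res.n_inliers / res.n_matched)
        assert len(res.l1_scores) == 8

    def test_bit_identical_determinism(self, session_pair):
        moving, template, _ = session_pair
        kwargs = dict(backend_name="orb", n_repeats=5, seed=3, max_tilt_index=1,
                      ransac_iterations=3000)
        r1 = fa.align_fov(moving.image, template.image, moving.mask.image,
                          template.mask.image, **kwargs)
        r2 = fa.align_fov(moving.image, template.image, moving.mask.image,
                          template.mask.image, **kwargs)
        assert _strip_arrays(r1) == _strip_arrays(r2)

    def test_uncorrelated_noise_fails(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 255, (96, 96)).astype(np.uint8)
        b = rng.integers(0, 255, (96, 96)).astype(np.uint8)
        mask = np.zeros((96, 96), np.uint8)
        mask[10:20, 10:20] = 255
        with pytest.raises(fa.AlignmentError):
            fa.align_fov(a, b, mask, mask, backend_name="sift", n_repeats=3,
                         seed=0, max_tilt_index=0, ransac_iterations=1000)

    def test_mask_geometry_validated(self, session_pair):
        moving, template, _ = session_pair
        bad = np.zeros((10, 10), np.uint8)
        with pytest.raises(ValueError, match="geometry"):
            fa.align_fov(moving.image, template.image, bad, template.mask.image,
                         backend_name="orb", n_repeats=2, seed=0)

    def test_affine_simulation_gains_inliers_on_tilted_pair(self, session_pair):
        moving, template, _ = session_pair
        inliers = {}
        for sim in (True, False):
            try:
                res = fa.align_fov(moving.image, template.image, moving.mask.image,
                                   template.mask.image, backend_name="brief",
                                   n_repeats=5, seed=5, affine_simulation=sim,
                                   max_tilt_index=2, ransac_iterations=3000)
                inliers[sim] = res.n_inliers
            except fa.AlignmentError:
                inliers[sim] = 0
        assert inliers[True] >= inliers[False]
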