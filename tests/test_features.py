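import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.transform import AffineTransform as SkAffine

import fovalign as fa
from fovalign.features import RansacError


def nndr_oracle(a, b, ratio, metric):
    """Exhaustive two-nearest-neighbor matching, the reference for match_nndr."""
    d = cdist(a.astype(float), b.astype(float),
              metric="euclidean" if metric == "euclidean" else "hamming")
    if metric == "hamming":
        d = np.rint(d * a.shape[1])
    keep = []
    for i in range(len(a)):
        order = np.argsort(d[i], kind="stable")
        d1, d2 = d[i][order[0]], d[i][order[1]]
        if d2 > 0 and d1 / d2 < ratio:
            keep.append((i, order[0]))
    return np.array(keep, dtype=int).reshape(-1, 2)


class TestDetect:
    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="unknown backend"):
            fa.detect_and_describe(np.zeros((64, 64), np.uint8), "surf64")

    def test_uniform_image_gives_no_keypoints(self):
        for backend in fa.available_backends():
            fs = fa.detect_and_describe(np.full((128, 128), 80, np.uint8), backend)
            assert len(fs) == 0

    def test_detection_is_deterministic(self, blob_image):
        img, _ = blob_image
        for backend in fa.available_backends():
            f1 = fa.detect_and_describe(img, backend)
            f2 = fa.detect_and_describe(img, backend)
            assert np.array_equal(f1.xy, f2.xy)
            assert np.array_equal(f1.descriptors, f2.descriptors)

    def test_keypoints_land_near_blob_centers(self, blob_image):
        img, centers = blob_image
        for backend in fa.available_backends():
            fs = fa.detect_and_describe(img, backend)
            assert len(fs) > 0
            d = np.linalg.norm(fs.xy[:, None, :] - centers[None], axis=2)
            assert d.min() < 3.0, backend

    def test_metric_tags(self, blob_image):
        img, _ = blob_image
        assert fa.detect_and_describe(img, "sift").metric == "euclidean"
        assert fa.detect_and_describe(img, "orb").metric == "hamming"
        assert fa.detect_and_describe(img, "brief").metric == "hamming"


class TestNNDR:
    def test_exact_duplicate_is_kept_with_zero_ratio(self):
        v = np.ones((1, 8), np.float32)
        b = np.vstack([v, 3 * v])
        ms = fa.match_nndr(v, b, 0.75)
        assert ms.pairs.tolist() == [[0, 0]]
        assert ms.ratios[0] == 0.0

    def test_ratio_above_threshold_rejected(self):
        a = np.zeros((1, 2), np.float32)
        b = np.array([[0.8, 0.0], [1.0, 0.0]], np.float32)  # ratio exactly 0.8
        assert len(fa.match_nndr(a, b, 0.75)) == 0
        assert len(fa.match_nndr(a, b, 0.85)) == 1

    def test_needs_two_rows_on_b_side(self):
        a = np.zeros((3, 4), np.float32)
        with pytest.raises(ValueError):
            fa.match_nndr(a, np.zeros((1, 4), np.float32), 0.75)

    def test_metric_mismatch_rejected(self):
        fs_f = fa.FeatureSet(xy=np.zeros((2, 2)), descriptors=np.zeros((2, 8), np.float32),
                             metric="euclidean", backend="sift")
        fs_b = fa.FeatureSet(xy=np.zeros((2, 2)), descriptors=np.zeros((2, 8), bool),
                             metric="hamming", backend="orb")
        with pytest.raises(ValueError, match="metric mismatch"):
            fa.match_nndr(fs_f, fs_b)

    @pytest.mark.parametrize("metric", ["euclidean", "hamming"])
    def test_oracle_equivalence_200x200(self, metric):
        rng = np.random.default_rng(11)
        if metric == "euclidean":
            a = rng.normal(size=(200, 128)).astype(np.float32)
            b = rng.normal(size=(200, 128)).astype(np.float32)
        else:
            a = rng.integers(0, 2, (200, 256)).astype(bool)
            b = rng.integers(0, 2, (200, 256)).astype(bool)
        ms = fa.match_nndr(a, b, 0.75, metric=metric)
        assert np.array_equal(ms.pairs, nndr_oracle(a, b, 0.75, metric))

    def test_invariant_under_permutation_of_b(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(50, 32)).astype(np.float32)
        b = rng.normal(size=(80, 32)).astype(np.float32)
        perm = rng.permutation(80)
        m1 = fa.match_nndr(a, b, 0.75)
        m2 = fa.match_nndr(a, b[perm], 0.75)
        remapped = perm[m2.pairs[:, 1]]
        assert np.array_equal(m1.pairs[:, 0], m2.pairs[:, 0])
        assert np.array_equal(m1.pairs[:, 1], remapped)


TRUE = fa.AffineTransform2D(a=1.1, b=0.2, c=-0.15, d=0.95, e=20.0, f=-7.0)


def inlier_outlier_problem(seed, n_in=60, n_out=40, noise=0.3, thresh=3.0):
    """Known-affine inliers plus rejection-sampled gross outliers."""
    rng = np.random.default_rng(seed)
    src_in = rng.uniform(0, 512, (n_in, 2))
    dst_in = TRUE.apply(src_in) + rng.normal(0, noise, (n_in, 2))
    src_out, dst_out = [], []
    while len(src_out) < n_out:
        s = rng.uniform(0, 512, 2)
        d = rng.uniform(0, 512, 2)
        if np.linalg.norm(TRUE.apply(s)[0] - d) > 2 * thresh:
            src_out.append(s)
            dst_out.append(d)
    src = np.vstack([src_in, src_out])
    dst = np.vstack([dst_in, dst_out])
    return src, dst


class TestRansac:
    def test_three_exact_points_recover_affine_any_seed(self):
        src = np.array([[0, 0], [100, 0], [0, 100]], float)
        dst = TRUE.apply(src)
        for seed in range(5):
            model, inl = fa.estimate_transform_ransac(src, dst, rng_seed=seed)
            assert np.abs(model.matrix - TRUE.matrix).max() < 1e-6
            assert inl.all()

    def test_rejects_all_outliers_with_noise(self):
        src, dst = inlier_outlier_problem(seed=100)
        model, inl = fa.estimate_transform_ransac(src, dst, n_iterations=10_000,
                                                  rng_seed=0)
        assert not inl[60:].any()
        assert inl[:60].sum() >= 55
        assert model.corner_displacement(TRUE, (512, 512)) < 0.5

    def test_agrees_with_skimage_least_squares_on_inliers(self):
        src, dst = inlier_outlier_problem(seed=101)
        model, inl = fa.estimate_transform_ransac(src, dst, n_iterations=10_000,
                                                  rng_seed=1)
        sk = SkAffine.from_estimate(src[inl], dst[inl])
        rss_ours = ((model.apply(src[inl]) - dst[inl]) ** 2).sum()
        rss_sk = ((sk(src[inl]) - dst[inl]) ** 2).sum()
        assert rss_ours <= rss_sk + 1e-9
        assert np.abs(model.homogeneous - sk.params).max() < 1e-2

    def test_fewer_than_three_matches_rejected(self):
        with pytest.raises(ValueError):
            fa.estimate_transform_ransac(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_collinear_points_degenerate(self):
        src = np.column_stack([np.arange(10.0), np.arange(10.0)])
        dst = src.copy()
        with pytest.raises(RansacError, match="degenerate|no model"):
            fa.estimate_transform_ransac(src, dst, n_iterations=500, rng_seed=0)

    def test_seeded_determinism(self):
        src, dst = inlier_outlier_problem(seed=102)
        m1, i1 = fa.estimate_transform_ransac(src, dst, n_iterations=5000, rng_seed=9)
        m2, i2 = fa.estimate_transform_ransac(src, dst, n_iterations=5000, rng_seed=9)
        assert m1 == m2
        assert np.array_equal(i1, i2)
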