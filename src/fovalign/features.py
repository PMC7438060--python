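"""Keypoint backends, NNDR matching and robust affine estimation.

Backends are interchangeable detector/descriptor pairs.  Float descriptors
(SIFT) are compared with the Euclidean metric, binary descriptors (ORB,
FAST+BRIEF) with the Hamming metric.  Putative matches are filtered by the
nearest-neighbor distance ratio (NNDR) test and a 6-parameter affine transform
is estimated by RANSAC with a confidence-based early exit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.feature import BRIEF, ORB, SIFT, corner_fast, corner_peaks

from .affine import AffineTransform2D

__all__ = [
    "FeatureSet",
    "MatchSet",
    "available_backends",
    "detect_and_describe",
    "match_nndr",
    "estimate_transform_ransac",
    "RansacError",
]

EUCLIDEAN = "euclidean"
HAMMING = "hamming"


@dataclass
class FeatureSet:
    """Keypoints plus descriptors for one image.

    ``xy`` holds (x=column, y=row) locations — view-frame right after
    detection, original-frame after backprojection.  ``metric`` tags the
    descriptor family (Euclidean for float, Hamming for binary descriptors).
    """

    xy: np.ndarray                     # (N, 2) float
    descriptors: np.ndarray            # (N, D) float32 or bool
    metric: str
    backend: str
    scale: np.ndarray = None           # (N,) px
    orientation: np.ndarray = None     # (N,) radians
    source_pose_index: np.ndarray = None  # (N,) int, index into the pose grid

    def __post_init__(self):
        n = len(self.xy)
        if self.scale is None:
            self.scale = np.ones(n)
        if self.orientation is None:
            self.orientation = np.zeros(n)
        if self.source_pose_index is None:
            self.source_pose_index = np.zeros(n, dtype=int)
        if len(self.descriptors) != n:
            raise ValueError("descriptor row count must equal keypoint count")

    def __len__(self) -> int:
        return len(self.xy)

    def take(self, idx) -> "FeatureSet":
        return FeatureSet(xy=self.xy[idx], descriptors=self.descriptors[idx],
                          metric=self.metric, backend=self.backend,
                          scale=self.scale[idx], orientation=self.orientation[idx],
                          source_pose_index=self.source_pose_index[idx])

    @classmethod
    def empty(cls, metric: str, backend: str, width: int = 0) -> "FeatureSet":
        dtype = bool if metric == HAMMING else np.float32
        return cls(xy=np.zeros((0, 2)), descriptors=np.zeros((0, width), dtype=dtype),
                   metric=metric, backend=backend)


@dataclass(frozen=True)
class MatchSet:
    """NNDR-filtered putative correspondences A -> B."""

    pairs: np.ndarray      # (M, 2) int, columns (index_in_A, index_in_B)
    distances: np.ndarray  # (M,) best-neighbor distance
    ratios: np.ndarray     # (M,) d1/d2

    def __len__(self) -> int:
        return len(self.pairs)


def _detect_sift(image: np.ndarray) -> FeatureSet:
    det = SIFT()
    try:
        det.detect_and_extract(image)
    except RuntimeError:  # no keypoints found
        return FeatureSet.empty(EUCLIDEAN, "sift", 128)
    kp = det.keypoints  # (row, col)
    return FeatureSet(xy=kp[:, ::-1].astype(float),
                      descriptors=det.descriptors.astype(np.float32),
                      metric=EUCLIDEAN, backend="sift",
                      scale=det.scales.astype(float) + 1.0,
                      orientation=det.orientations.astype(float))


def _detect_orb(image: np.ndarray) -> FeatureSet:
    det = ORB(n_keypoints=500)
    try:
        det.detect_and_extract(image.astype(float))
    except (RuntimeError, IndexError):
        return FeatureSet.empty(HAMMING, "orb", 256)
    kp = det.keypoints
    return FeatureSet(xy=kp[:, ::-1].astype(float), descriptors=det.descriptors,
                      metric=HAMMING, backend="orb",
                      scale=det.scales.astype(float),
                      orientation=det.orientations.astype(float))


def _detect_brief(image: np.ndarray) -> FeatureSet:
    img = image.astype(float)
    corners = corner_peaks(corner_fast(img, threshold=0.08), min_distance=5,
                           threshold_rel=0.0)
    extractor = BRIEF(patch_size=49, sigma=1.0)
    if len(corners) == 0:
        return FeatureSet.empty(HAMMING, "brief", 256)
    extractor.extract(img, corners)
    kept = corners[extractor.mask]
    if len(kept) == 0:
        return FeatureSet.empty(HAMMING, "brief", 256)
    return FeatureSet(xy=kept[:, ::-1].astype(float),
                      descriptors=extractor.descriptors,
                      metric=HAMMING, backend="brief")


_BACKENDS = {"sift": _detect_sift, "orb": _detect_orb, "brief": _detect_brief}


def available_backends() -> list[str]:
    """Names of the registered detector/descriptor backends."""
    return sorted(_BACKENDS)


def detect_and_describe(image: np.ndarray, backend_name: str) -> FeatureSet:
    """Detect keypoints and compute descriptors with the named backend.

    Deterministic for a fixed input and backend configuration.  A uniform
    image yields an empty feature set.
    """
    if backend_name not in _BACKENDS:
        raise ValueError(
            f"unknown backend {backend_name!r}; available: {available_backends()}")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("detect_and_describe expects a 2-D grayscale image")
    if min(img.shape) < 16:
        raise ValueError(f"image shape {img.shape} too small for the feature pyramid")
    return _BACKENDS[backend_name](img)


def _pairwise_sq_euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    d2 = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * (a @ b.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def _pairwise_hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # bit counts via float matmul: d = sum(a != b) = sum(a) + sum(b) - 2*a.b
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    d = af.sum(1)[:, None] + bf.sum(1)[None, :] - 2.0 * (af @ bf.T)
    return np.rint(d)


def match_nndr(descA: "FeatureSet | np.ndarray", descB: "FeatureSet | np.ndarray",
               ratio_threshold: float = 0.75, metric: str | None = None) -> MatchSet:
    """One-way (A -> B) nearest-neighbor distance-ratio matching.

    For every descriptor in A the two nearest descriptors in B are found under
    the set's metric; the best match is kept iff ``d1/d2 < ratio_threshold``.
    The output is invariant under permutation of B's rows (up to tie order).
    """
    if isinstance(descA, FeatureSet):
        if isinstance(descB, FeatureSet) and descA.metric != descB.metric:
            raise ValueError(
                f"metric mismatch: {descA.metric!r} vs {descB.metric!r}")
        metric = descA.metric
        a, b = descA.descriptors, descB.descriptors
    else:
        a, b = np.asarray(descA), np.asarray(descB)
        if metric is None:
            metric = HAMMING if a.dtype == bool else EUCLIDEAN
    if len(b) < 2:
        raise ValueError("NNDR needs at least 2 descriptors on the B side")
    if len(a) == 0:
        return MatchSet(pairs=np.zeros((0, 2), int), distances=np.zeros(0),
                        ratios=np.zeros(0))

    pairs, dists, ratios = [], [], []
    chunk = max(1, int(4e7 // max(len(b), 1)))
    for start in range(0, len(a), chunk):
        block = a[start:start + chunk]
        if metric == EUCLIDEAN:
            d = np.sqrt(_pairwise_sq_euclidean(block, b))
        elif metric == HAMMING:
            d = _pairwise_hamming(block, b)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        idx2 = np.argpartition(d, 1, axis=1)[:, :2]
        row = np.arange(len(block))[:, None]
        two = d[row, idx2]
        order = np.argsort(two, axis=1, kind="stable")
        two = two[row, order]
        best_idx = idx2[row, order][:, 0]
        d1, d2 = two[:, 0], two[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(d2 > 0, d1 / d2, np.inf)
        r = np.where((d2 == 0) & (d1 == 0), np.inf, r)
        keep = r < ratio_threshold
        pairs.append(np.column_stack([np.nonzero(keep)[0] + start, best_idx[keep]]))
        dists.append(d1[keep])
        ratios.append(r[keep])
    return MatchSet(pairs=np.concatenate(pairs).astype(int),
                    distances=np.concatenate(dists),
                    ratios=np.concatenate(ratios))


class RansacError(RuntimeError):
    """Raised when no valid affine model can be estimated."""


def _fit_affine_lstsq(src: np.ndarray, dst: np.ndarray) -> AffineTransform2D:
    x = np.column_stack([src, np.ones(len(src))])
    params, *_ = np.linalg.lstsq(x, dst, rcond=None)
    return AffineTransform2D(a=params[0, 0], b=params[1, 0], e=params[2, 0],
                             c=params[0, 1], d=params[1, 1], f=params[2, 1])


def estimate_transform_ransac(
    src: np.ndarray,
    dst: np.ndarray,
    n_iterations: int = 150_000,
    confidence: float = 0.999,
    reproj_threshold_px: float = 3.0,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[AffineTransform2D, np.ndarray]:
    """RANSAC estimation of the affine map src -> dst.

    Minimal samples of 3 correspondences are drawn until ``n_iterations`` is
    exhausted or the confidence bound on having seen an outlier-free sample is
    met.  The best model (most inliers; ties broken by residual sum) is refit
    by least squares on its inlier set and the refit model's inlier flags are
    returned.

    Raises ``ValueError`` for fewer than 3 matches and ``RansacError`` when all
    sampled triples are degenerate (collinear).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 3 or len(dst) != n:
        raise ValueError(f"RANSAC needs >= 3 matched points on both sides, got {n}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    src_h = np.column_stack([src, np.ones(n)])     # (n, 3)
    best_count = -1
    best_rss = np.inf
    best_inliers = None
    thresh2 = reproj_threshold_px ** 2
    trials_needed = n_iterations
    trials_done = 0
    any_valid = False
    log_outlier = np.log(max(1.0 - confidence, 1e-300))
    chunk = 512

    while trials_done < min(n_iterations, trials_needed):
        b = min(chunk, n_iterations - trials_done)
        samples = rng.integers(0, n, size=(b, 3))
        trials_done += b
        ok = ((samples[:, 0] != samples[:, 1]) & (samples[:, 0] != samples[:, 2])
              & (samples[:, 1] != samples[:, 2]))
        if not ok.any():
            continue
        s = samples[ok]
        xs = src_h[s]                               # (B, 3, 3)
        ys = dst[s]                                 # (B, 3, 2)
        dets = np.linalg.det(xs)
        nondeg = np.abs(dets) > 1e-9
        if not nondeg.any():
            continue
        xs, ys = xs[nondeg], ys[nondeg]
        any_valid = True
        params = np.linalg.solve(xs, ys)            # (B, 3, 2)
        resid = np.einsum("nk,bkj->bnj", src_h, params) - dst[None]
        err2 = (resid ** 2).sum(-1)                 # (B, n)
        inl = err2 <= thresh2
        counts = inl.sum(1)
        order = np.argmax(counts)
        if counts[order] > 0:
            rss = float(err2[order][inl[order]].sum())
            if counts[order] > best_count or (counts[order] == best_count and rss < best_rss):
                best_count = int(counts[order])
                best_rss = rss
                best_inliers = inl[order].copy()
        if best_count >= 3:
            w = best_count / n
            denom = np.log1p(-min(w ** 3, 1.0 - 1e-12))
            trials_needed = int(np.ceil(log_outlier / denom)) if denom < 0 else n_iterations

    if not any_valid:
        raise RansacError("all sampled minimal triples were degenerate (collinear points)")
    if best_inliers is None or best_count < 3:
        raise RansacError(
            f"RANSAC found no model with >= 3 inliers among {n} matches")

    model = _fit_affine_lstsq(src[best_inliers], dst[best_inliers])
    err = ((model.apply(src) - dst) ** 2).sum(1)
    inliers = err <= thresh2
    if inliers.sum() >= 3 and inliers.sum() != best_count:
        model = _fit_affine_lstsq(src[inliers], dst[inliers])
        err = ((model.apply(src) - dst) ** 2).sum(1)
        inliers = err <= thresh2
    if abs(model.determinant) < 1e-12:
        raise RansacError("estimated transform is singular")
    return model, inliers
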