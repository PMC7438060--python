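"""Cross-session FOV alignment with repeated RANSAC and L1-based selection.

The full pipeline: affine-simulate both images over the pose grid, detect and
describe keypoints on every simulated view, backproject them into the original
frames and pool them; match once with NNDR; then run RANSAC ``n_repeats``
times with per-repeat seeds and keep the transform that minimizes the L1 norm
of the disagreement between the warped moving ROI mask and the template ROI
mask.  Randomized estimation alone is not reproducible when the inlier ratio
is low; the mask-based arg-min makes the selected transform stable and
replayable from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .affine import AffineTransform2D, backproject_keypoints, sample_pose_grid, simulate_view
from .features import (EUCLIDEAN, FeatureSet, MatchSet, RansacError,
                       detect_and_describe, estimate_transform_ransac, match_nndr)

__all__ = [
    "AlignmentResult",
    "AlignmentError",
    "align_fov",
    "extract_pooled_features",
    "l1_mask_score",
    "apply_transform",
    "clahe_preprocess",
]


class AlignmentError(RuntimeError):
    pass


@dataclass
class AlignmentResult:
    """Outcome of one moving-to-template alignment with full repeat provenance."""

    transform: AffineTransform2D
    n_inliers: int
    n_matched: int
    n_features_moving: int
    n_features_template: int
    inlier_ratio: float
    l1_scores: list
    selected_repeat: int
    backend_name: str
    seed: int
    repeat_transforms: list = field(default_factory=list)
    repeat_inliers: list = field(default_factory=list)


def apply_transform(transform: AffineTransform2D, image_or_mask: np.ndarray,
                    interpolation: str = "bilinear",
                    output_shape=None) -> np.ndarray:
    """Warp an image or mask by ``transform`` into the template frame.

    Masks should use ``interpolation='nearest'`` so values stay in {0, 255};
    intensity images use bilinear.  Out-of-frame pixels become 0.
    """
    if abs(transform.determinant) < 1e-15:
        raise ValueError("transform is not invertible")
    arr = np.asarray(image_or_mask)
    order = {"nearest": 0, "bilinear": 1}[interpolation]
    if output_shape is None:
        output_shape = arr.shape
    inv = sktransform.AffineTransform(matrix=transform.inverse().homogeneous)
    out = sktransform.warp(arr.astype(float), inv, output_shape=output_shape,
                           order=order, mode="constant", cval=0.0,
                           preserve_range=True)
    return out.astype(arr.dtype) if order == 0 else out


def l1_mask_score(transform: AffineTransform2D, moving_mask_raw: np.ndarray,
                  template_mask_raw: np.ndarray) -> float:
    """L1 norm of the mask disagreement after warping the moving mask.

    The moving 0/255 mask is warped (nearest-neighbor) into the template frame
    and the sum of absolute intensity differences is taken over the whole
    frame.  For binary masks this equals 255 times the number of
    symmetric-difference pixels, i.e. the disagreement exactly where a neuron
    appears in one mask but not the other.
    """
    moving = np.asarray(moving_mask_raw)
    tmpl = np.asarray(template_mask_raw)
    warped = apply_transform(transform, moving, interpolation="nearest",
                             output_shape=tmpl.shape)
    return float(np.abs(warped.astype(np.int64) - tmpl.astype(np.int64)).sum())


def clahe_preprocess(image: np.ndarray, tile_grid: tuple[int, int] = (8, 8),
                     clip_limit: float = 1.0) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization for 8-bit images.

    The image is divided into a ``tile_grid`` of blocks; each block's 256-bin
    histogram is clipped at ``clip_limit`` times the mean bin height (excess
    redistributed uniformly) and turned into an equalization lookup table.
    Pixels are remapped by bilinear interpolation between the four surrounding
    block tables, which removes block-boundary artifacts.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("CLAHE expects a 2-D grayscale image")
    if img.dtype != np.uint8:
        raise ValueError("CLAHE expects an 8-bit image")
    gy, gx = tile_grid
    h, w = img.shape
    th, tw = int(np.ceil(h / gy)), int(np.ceil(w / gx))
    pad = np.pad(img, ((0, th * gy - h), (0, tw * gx - w)), mode="reflect")

    tiles = pad.reshape(gy, th, gx, tw).transpose(0, 2, 1, 3)
    luts = np.empty((gy, gx, 256), dtype=np.float64)
    npix = th * tw
    clip = max(clip_limit * npix / 256.0, 1.0)
    for i in range(gy):
        for j in range(gx):
            hist = np.bincount(tiles[i, j].ravel(), minlength=256).astype(float)
            excess = np.clip(hist - clip, 0, None).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = hist.cumsum()
            cdf_min = cdf[np.nonzero(hist)[0][0]]
            denom = max(npix - cdf_min, 1e-12)
            luts[i, j] = np.clip((cdf - cdf_min) / denom * 255.0, 0.0, 255.0)

    # bilinear blend of the 4 surrounding tile LUTs at each pixel
    yy, xx = np.mgrid[0:h, 0:w]
    fy = (yy + 0.5) / th - 0.5
    fx = (xx + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, gy - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, gx - 1)
    y1 = np.clip(y0 + 1, 0, gy - 1)
    x1 = np.clip(x0 + 1, 0, gx - 1)
    wy = np.clip(fy - y0, 0.0, 1.0)
    wx = np.clip(fx - x0, 0.0, 1.0)
    v = img
    out = ((1 - wy) * (1 - wx) * luts[y0, x0, v] + (1 - wy) * wx * luts[y0, x1, v]
           + wy * (1 - wx) * luts[y1, x0, v] + wy * wx * luts[y1, x1, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _dedupe(fs: FeatureSet) -> FeatureSet:
    """Collapse keypoints under 1 px apart with identical descriptors.

    Pooling backprojected keypoints across overlapping simulated views
    produces exact duplicates near the frontal pose that would bias RANSAC
    sampling; only one representative per (rounded location, descriptor) is
    kept, earliest view first.
    """
    if len(fs) <= 1:
        return fs
    seen: dict = {}
    keep = []
    for i in range(len(fs)):
        key = (int(round(fs.xy[i, 0])), int(round(fs.xy[i, 1])),
               fs.descriptors[i].tobytes())
        if key not in seen:
            seen[key] = i
            keep.append(i)
    return fs.take(np.array(keep, dtype=int))


def extract_pooled_features(image: np.ndarray, backend_name: str,
                            max_tilt_index: int = 5) -> FeatureSet:
    """Simulate the pose grid, detect per view, backproject and pool.

    Each keypoint is tagged with the index of the (tilt, phi) pose it was
    detected under; pose index 0 is the frontal (unsimulated) view, so plain
    single-view matching is the subset ``source_pose_index == 0``.
    """
    grid = sample_pose_grid(max_tilt_index)
    pooled: list[FeatureSet] = []
    for pose_idx, (tilt, phi) in enumerate(grid):
        view = simulate_view(image, tilt, phi)
        fs = detect_and_describe(view.image, backend_name)
        if len(fs) == 0:
            continue
        back, kept = backproject_keypoints(fs.xy, view, image.shape)
        fs = fs.take(kept)
        fs.xy = back
        fs.source_pose_index = np.full(len(fs), pose_idx, dtype=int)
        pooled.append(fs)
    if not pooled:
        return detect_and_describe(image, backend_name)
    merged = FeatureSet(
        xy=np.concatenate([f.xy for f in pooled]),
        descriptors=np.concatenate([f.descriptors for f in pooled]),
        metric=pooled[0].metric, backend=backend_name,
        scale=np.concatenate([f.scale for f in pooled]),
        orientation=np.concatenate([f.orientation for f in pooled]),
        source_pose_index=np.concatenate([f.source_pose_index for f in pooled]))
    return _dedupe(merged)


def align_fov(
    moving_image: np.ndarray,
    template_image: np.ndarray,
    moving_mask_raw: np.ndarray,
    template_mask_raw: np.ndarray,
    backend_name: str = "sift",
    n_repeats: int = 100,
    seed: int = 0,
    *,
    affine_simulation: bool = True,
    max_tilt_index: int = 5,
    nndr_ratio: float = 0.75,
    ransac_iterations: int = 150_000,
    ransac_confidence: float = 0.999,
    reproj_threshold_px: float = 3.0,
    clahe: bool = False,
) -> AlignmentResult:
    """Align a moving session FOV to the template session FOV.

    Features are computed once per image pair; NNDR matching is deterministic
    and shared across repeats; RANSAC is re-run ``n_repeats`` times with seeds
    ``seed + i``, each candidate transform is scored by :func:`l1_mask_score`
    against the raw ROI masks, and the arg-min transform wins (ties: earliest
    repeat).  Set ``affine_simulation=False`` for the plain single-view
    backend (the feature-based rather than fully affine invariant method).
    """
    moving = np.asarray(moving_image)
    template = np.asarray(template_image)
    if moving.dtype != template.dtype:
        raise ValueError("moving and template images must share a bit-depth")
    for name, msk, img in (("moving", moving_mask_raw, moving),
                           ("template", template_mask_raw, template)):
        msk = np.asarray(msk)
        if msk.shape != np.asarray(img).shape:
            raise ValueError(f"{name} mask geometry {msk.shape} != image {np.asarray(img).shape}")
        if not np.isin(np.unique(msk), (0, 255)).all():
            raise ValueError(f"{name} mask must be binary with values 0/255")
    if clahe:
        moving = clahe_preprocess(moving)
        template = clahe_preprocess(template)

    if affine_simulation:
        feat_m = extract_pooled_features(moving, backend_name, max_tilt_index)
        feat_t = extract_pooled_features(template, backend_name, max_tilt_index)
    else:
        feat_m = detect_and_describe(moving, backend_name)
        feat_t = detect_and_describe(template, backend_name)

    if len(feat_m) == 0 or len(feat_t) < 2:
        raise AlignmentError(
            f"insufficient features: moving={len(feat_m)}, template={len(feat_t)}")
    matches = match_nndr(feat_m, feat_t, ratio_threshold=nndr_ratio)
    if len(matches) < 3:
        raise AlignmentError(
            f"insufficient NNDR matches ({len(matches)}) from "
            f"{len(feat_m)}/{len(feat_t)} pooled features")

    src = feat_m.xy[matches.pairs[:, 0]]
    dst = feat_t.xy[matches.pairs[:, 1]]
    l1_scores: list[float] = []
    transforms: list = []
    inlier_counts: list[int] = []
    for i in range(n_repeats):
        try:
            model, inl = estimate_transform_ransac(
                src, dst, n_iterations=ransac_iterations,
                confidence=ransac_confidence,
                reproj_threshold_px=reproj_threshold_px, rng_seed=seed + i)
        except RansacError:
            transforms.append(None)
            inlier_counts.append(0)
            l1_scores.append(float("inf"))
            continue
        transforms.append(model)
        inlier_counts.append(int(inl.sum()))
        l1_scores.append(l1_mask_score(model, moving_mask_raw, template_mask_raw))

    if all(t is None for t in transforms):
        raise AlignmentError(
            f"all {n_repeats} repeats failed: {len(matches)} matches of "
            f"{len(feat_m)}/{len(feat_t)} features never yielded a valid model")
    selected = int(np.argmin(l1_scores))
    winner = transforms[selected]
    if abs(winner.determinant) < 1e-12:
        raise AlignmentError("winning transform is degenerate (non-invertible)")
    n_matched = len(matches)
    n_inl = inlier_counts[selected]
    return AlignmentResult(
        transform=winner,
        n_inliers=n_inl,
        n_matched=n_matched,
        n_features_moving=len(feat_m),
        n_features_template=len(feat_t),
        inlier_ratio=n_inl / n_matched if n_matched else 0.0,
        l1_scores=l1_scores,
        selected_repeat=selected,
        backend_name=backend_name,
        seed=seed,
        repeat_transforms=transforms,
        repeat_inliers=inlier_counts,
    )
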