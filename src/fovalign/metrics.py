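"""ROI-mask construction, filtering, and alignment-quality metrics.

Neuron masks are binary images (255 inside a neuron footprint, 0 elsewhere).
Alignment quality is scored by the Pearson correlation of the flattened mask
pair; image quality by a Fourier-spectrum sharpness ratio and by the number of
neurons two sessions share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .affine import AffineTransform2D

__all__ = [
    "ROIMask",
    "SharpnessReport",
    "binarize_and_filter",
    "mask_correlation",
    "sharpness",
    "count_common_neurons",
]


@dataclass
class ROIMask:
    """Binary neuron mask plus per-ROI pixel bookkeeping.

    ``image`` holds values in {0, 255}; ``rois`` is a list of (N_i, 2) integer
    arrays of (row, col) pixel coordinates, one per ROI; ``centroids`` is an
    (n_roi, 2) array of (x, y) centroids.
    """

    image: np.ndarray
    rois: list
    centroids: np.ndarray

    @property
    def n_rois(self) -> int:
        return len(self.rois)


def _is_binary(mask: np.ndarray) -> bool:
    if mask.dtype == bool:
        return True
    vals = np.unique(mask)
    return np.isin(vals, (0, 1, 255)).all()


def binarize_and_filter(label_mask: np.ndarray, min_pixels: int = 60) -> ROIMask:
    """Build a 0/255 ROI mask, dropping components smaller than ``min_pixels``.

    Binary inputs are re-labelled by 8-connected components; integer label
    images keep their label identities.  Components with at least
    ``min_pixels`` pixels survive (a 60-px ROI passes the default filter, a
    59-px ROI does not) — the size floor screens out dendritic spines and
    segmentation fragments that would otherwise pollute the mask.
    """
    m = np.asarray(label_mask)
    if m.ndim != 2:
        raise ValueError("expected a 2-D label or binary mask")
    if np.issubdtype(m.dtype, np.floating):
        m = m.astype(np.int64)
    if (m < 0).any():
        raise ValueError("labels must be nonnegative (0 = background)")
    labels = measure.label(m > 0, connectivity=2) if _is_binary(m) else m

    out = np.zeros(m.shape, dtype=np.uint8)
    rois: list[np.ndarray] = []
    cents: list[tuple[float, float]] = []
    for region in measure.regionprops(labels):
        if region.area < min_pixels:
            continue
        coords = region.coords  # (N, 2) as (row, col)
        out[coords[:, 0], coords[:, 1]] = 255
        rois.append(coords)
        cy, cx = region.centroid
        cents.append((cx, cy))
    centroids = np.array(cents, dtype=float).reshape(-1, 2)
    return ROIMask(image=out, rois=rois, centroids=centroids)


def _as_array(mask) -> np.ndarray:
    return np.asarray(mask.image if isinstance(mask, ROIMask) else mask)


def mask_correlation(maskA, maskB) -> float:
    """Pearson correlation of the two flattened masks.

    The 2-D masks are reshaped to 1-D vectors and the standard Pearson linear
    correlation coefficient is computed.  Pearson r is invariant to the 0/255
    vs 0/1 coding.  A constant mask has zero variance and makes the
    coefficient undefined; this is reported as an error rather than as 0.
    """
    a = _as_array(maskA).astype(float).ravel()
    b = _as_array(maskB).astype(float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for name, v in (("first", a), ("second", b)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"{name} mask is constant; Pearson correlation is undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class SharpnessReport:
    """Fraction of spectrum bins above the template-derived threshold."""

    value: float           # in (0, 1]; lower = more blurred
    threshold: float       # M / 1000
    template_max_M: float  # max magnitude of the template's centered spectrum


def sharpness(image: np.ndarray, template: np.ndarray) -> SharpnessReport:
    """Spectral sharpness of ``image`` relative to ``template``.

    ``M`` is the maximum modulus of the template's centered 2-D Fourier
    spectrum; the sharpness value is the fraction of the image's spectrum bins
    whose modulus exceeds ``M/1000``.  Blur removes high-frequency energy, so
    blurrier images score lower.
    """
    img = np.asarray(image, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if img.shape != tpl.shape:
        raise ValueError(f"image and template shapes differ: {img.shape} vs {tpl.shape}")
    m = float(np.abs(np.fft.fftshift(np.fft.fft2(tpl))).max())
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    count = int((spec > m / 1000.0).sum())
    return SharpnessReport(value=count / img.size, threshold=m / 1000.0,
                           template_max_M=m)


def count_common_neurons(maskA: ROIMask, maskB: ROIMask,
                         transform: AffineTransform2D | None = None,
                         centroid_radius_px: float = 5.0):
    """Count neurons shared by two masks via transformed-centroid proximity.

    A's ROI centroids are mapped through ``transform`` (identity if None) into
    B's frame; an A-ROI and a B-ROI are paired when their centroids are within
    ``centroid_radius_px``, using greedy nearest-first one-to-one assignment.
    Returns ``(count, pairs)`` with ``pairs`` a list of (index_in_A,
    index_in_B).  This is an algorithmic stand-in for manual common-neuron
    curation, controlled by the pairing radius.
    """
    if transform is None:
        transform = AffineTransform2D.identity()
    if abs(transform.determinant) < 1e-15:
        raise ValueError("transform must be invertible")
    if maskA.n_rois == 0 or maskB.n_rois == 0:
        return 0, []
    ca = transform.apply(maskA.centroids)
    cb = maskB.centroids
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    used_a = np.zeros(len(ca), dtype=bool)
    used_b = np.zeros(len(cb), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), len(cb))
        if d[i, j] > centroid_radius_px:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    return len(pairs), pairs
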