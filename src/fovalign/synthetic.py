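"""Synthetic two-photon FOV scenes with ground-truth cross-session transforms.

A scene is a layout of soma-like anisotropic Gaussian blobs.  A session render
warps the scene by a known affine camera pose, keeps only a subset of neurons
active (sessions share neurons only partially), multiplies in a smooth uneven
background, blurs, adds sensor noise and quantizes to 8 bits.  The paired ROI
mask is rendered noiselessly from the same subset and transform, so every
stage of the registration pipeline can be scored against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .affine import AffinePose, AffineTransform2D, compose_affine
from .metrics import ROIMask, binarize_and_filter

__all__ = [
    "SyntheticScene",
    "SessionRender",
    "BenchmarkConfig",
    "BenchmarkPair",
    "generate_scene",
    "render_session",
    "benchmark_suite",
    "common_roi_mask",
]

# blob support = pixels above amplitude/5, i.e. Mahalanobis q <= 2*ln(5)
_Q_SUPPORT = 2.0 * math.log(5.0)


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth neuron layout in the frontal (template) frame.

    ``texture`` is a smooth zero-mean unit-variance random field emulating the
    structured neuropil/dendrite background of a mean two-photon image; it is
    anchored to the scene, so sessions viewing the scene from different poses
    see the same texture warped consistently.  Without it every neuron looks
    like every other neuron and descriptor matching has nothing distinctive to
    lock onto, which real mean-FOV images do not suffer from.
    """

    frame_shape: tuple
    neuron_centers: np.ndarray      # (n, 2) as (x, y)
    neuron_covariances: np.ndarray  # (n, 2, 2) px^2
    neuron_amplitudes: np.ndarray   # (n,) intensity units
    texture: np.ndarray             # (h, w) float, zero mean, unit variance
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_centers)


@dataclass
class SessionRender:
    """One rendered imaging session plus its ground truth."""

    image: np.ndarray                   # 2-D uint8
    mask: ROIMask                       # filtered 0/255 mask in the session frame
    true_transform: AffineTransform2D   # frontal scene frame -> session frame
    active_subset: np.ndarray           # scene neuron indices rendered
    visible_ids: np.ndarray             # scene neuron index per mask ROI (post filter)
    blur_sigma: float
    background_params: dict
    noise_sigma: float
    seed: int


def generate_scene(n_neurons: int = 25, frame_shape=(512, 512), seed: int = 0,
                   min_spacing: float = 18.0, margin: float = 24.0) -> SyntheticScene:
    """Rejection-sample a neuron layout with a minimum center spacing.

    Blob axes are drawn in [2.8, 4.5] px so every noiseless ROI covers at
    least 60 px at the amplitude/5 support threshold; the spacing floor keeps
    ROIs from merging.  Fully reproducible from ``seed``.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    h, w = frame_shape
    if w - 2 * margin < min_spacing or h - 2 * margin < min_spacing:
        raise ValueError(f"frame {frame_shape} too small for spacing {min_spacing}")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10_000 * n_neurons
    while len(centers) < n_neurons:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_neurons} neurons with spacing {min_spacing} "
                f"in frame {frame_shape} after {max_attempts} attempts")
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.linalg.norm(cand - c) >= min_spacing for c in centers):
            centers.append(cand)
    centers_arr = np.array(centers)

    covs = np.empty((n_neurons, 2, 2))
    for i in range(n_neurons):
        s1, s2 = rng.uniform(2.8, 4.5, size=2)
        ang = rng.uniform(0, math.pi)
        c, s = math.cos(ang), math.sin(ang)
        r = np.array([[c, -s], [s, c]])
        covs[i] = r @ np.diag([s1 ** 2, s2 ** 2]) @ r.T
    amps = rng.uniform(150.0, 250.0, size=n_neurons)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    texture = (texture - texture.mean()) / texture.std()
    return SyntheticScene(frame_shape=tuple(frame_shape), neuron_centers=centers_arr,
                          neuron_covariances=covs, neuron_amplitudes=amps,
                          texture=texture, seed=seed)


def _centered_transform(scene_shape, pose: AffinePose | None,
                        translation=(0.0, 0.0)) -> AffineTransform2D:
    """Pose transform anchored at the frame center, plus a translation."""
    if pose is None:
        lin = np.eye(2)
    else:
        lin = compose_affine(pose).linear
    h, w = scene_shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift = center - lin @ center + np.asarray(translation, dtype=float)
    return AffineTransform2D.from_linear(lin, translation=shift)


def _render_blobs(scene: SyntheticScene, transform: AffineTransform2D,
                  subset: np.ndarray):
    """Analytic warp of the Gaussian blob field (no resampling error).

    Returns the float intensity field and an integer label image of the
    amplitude/5 support of each rendered neuron (labels are scene indices +1).
    """
    h, w = scene.frame_shape
    img = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    lin = transform.linear
    for idx in subset:
        mu = transform.apply(scene.neuron_centers[idx])[0]
        cov = lin @ scene.neuron_covariances[idx] @ lin.T
        amp = scene.neuron_amplitudes[idx]
        extent = 3.0 * math.sqrt(float(np.linalg.eigvalsh(cov).max()))
        x0 = max(int(math.floor(mu[0] - extent)), 0)
        x1 = min(int(math.ceil(mu[0] + extent)) + 1, w)
        y0 = max(int(math.floor(mu[1] - extent)), 0)
        y1 = min(int(math.ceil(mu[1] + extent)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.stack([xx - mu[0], yy - mu[1]], axis=-1)
        prec = np.linalg.inv(cov)
        q = np.einsum("...i,ij,...j->...", d, prec, d)
        img[y0:y1, x0:x1] += amp * np.exp(-0.5 * q)
        support = q <= _Q_SUPPORT
        labels[y0:y1, x0:x1][support] = idx + 1
    return img, labels


def _background_field(shape, amplitude: float, rng: np.random.Generator) -> tuple:
    """Smooth multiplicative brightness field: 1 + sum of low-freq cosines."""
    h, w = shape
    if amplitude <= 0:
        return np.ones(shape), {"amplitude": 0.0, "components": []}
    n_comp = int(rng.integers(2, 5))
    yy, xx = np.mgrid[0:h, 0:w]
    field = np.ones(shape)
    comps = []
    for _ in range(n_comp):
        wavelength = rng.uniform(0.5, 2.0) * min(h, w)
        ang = rng.uniform(0, 2 * math.pi)
        fx = math.cos(ang) / wavelength
        fy = math.sin(ang) / wavelength
        phase = rng.uniform(0, 2 * math.pi)
        a = amplitude / n_comp
        field += a * np.cos(2 * math.pi * (fx * xx + fy * yy) + phase)
        comps.append({"a": a, "fx": fx, "fy": fy, "phase": phase})
    return field, {"amplitude": amplitude, "components": comps}


def render_session(
    scene: SyntheticScene,
    pose: AffinePose | None = None,
    translation=(0.0, 0.0),
    active_fraction: float = 1.0,
    blur_sigma: float = 0.0,
    background_amplitude: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    active_indices: np.ndarray | None = None,
    baseline: float = 25.0,
    texture_amplitude: float = 12.0,
    min_roi_pixels: int = 60,
) -> SessionRender:
    """Render one imaging session of a scene under a known camera pose.

    The blob field is warped analytically by the composed transform (pose
    anchored at the frame center, then translated), a low-frequency
    multiplicative background is applied, then Gaussian blur, Gaussian sensor
    noise and 8-bit quantization.  The ROI mask is rendered noiselessly from
    the same subset and transform and passed through the size filter.
    ``active_indices`` overrides the random ``active_fraction`` subset when the
    caller needs exact overlap control between sessions.
    """
    if not (0.0 < active_fraction <= 1.0):
        raise ValueError("active_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = scene.n_neurons
    if active_indices is None:
        k = max(1, int(round(active_fraction * n)))
        active = np.sort(rng.choice(n, size=k, replace=False))
    else:
        active = np.sort(np.asarray(active_indices, dtype=int))
    transform = _centered_transform(scene.frame_shape, pose, translation)

    blobs, labels = _render_blobs(scene, transform, active)
    field, bg_params = _background_field(scene.frame_shape, background_amplitude, rng)
    body = baseline + blobs
    if texture_amplitude > 0:
        inv = sktransform.AffineTransform(matrix=transform.inverse().homogeneous)
        warped_tex = sktransform.warp(scene.texture, inv,
                                      output_shape=scene.frame_shape, order=1,
                                      mode="constant", cval=0.0, preserve_range=True)
        body = body + texture_amplitude * warped_tex
    img = body * field
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mask = binarize_and_filter(labels, min_pixels=min_roi_pixels)
    visible = np.array([int(labels[tuple(r[0])]) - 1 for r in mask.rois], dtype=int)
    return SessionRender(image=img8, mask=mask, true_transform=transform,
                         active_subset=active, visible_ids=visible,
                         blur_sigma=blur_sigma, background_params=bg_params,
                         noise_sigma=noise_sigma, seed=seed)


def common_roi_mask(render: SessionRender, neuron_ids) -> np.ndarray:
    """0/255 mask restricted to the ROIs of the given scene neuron ids."""
    wanted = {int(i) for i in list(neuron_ids)}
    out = np.zeros(render.mask.image.shape, dtype=np.uint8)
    for roi, nid in zip(render.mask.rois, render.visible_ids):
        if int(nid) in wanted:
            out[roi[:, 0], roi[:, 1]] = 255
    return out


@dataclass(frozen=True)
class BenchmarkConfig:
    """Stratified benchmark conditions (angles in degrees, lengths in px)."""

    n_pairs_per_stratum: int = 10
    n_neurons: int = 25
    frame_shape: tuple = (256, 256)
    easy_tilt_deg: tuple = (5.0, 15.0)
    easy_spin_deg: tuple = (-10.0, 10.0)
    easy_translation_px: tuple = (-10.0, 10.0)
    easy_overlap: float = 0.8
    easy_blur_sigma: float = 0.0
    easy_background: float = 0.1
    easy_noise_sigma: float = 3.0
    stress_tilt_deg: tuple = (35.0, 45.0)
    stress_spin_deg: tuple = (-15.0, 15.0)
    stress_translation_px: tuple = (-15.0, 15.0)
    stress_overlap: float = 0.3
    stress_blur_sigma: tuple = (2.0, 3.0)
    stress_background: float = 0.4
    stress_noise_sigma: float = 6.0


@dataclass
class BenchmarkPair:
    """A rendered session pair plus its ground-truth alignment."""

    pair_id: str
    stratum: str
    scene: SyntheticScene
    template: SessionRender
    moving: SessionRender
    true_transform: AffineTransform2D   # moving frame -> template frame
    shared_ids: np.ndarray              # scene indices active in both sessions


def _split_subsets(n: int, overlap: float, rng: np.random.Generator):
    """Index sets for two sessions with an exact shared-neuron count."""
    n_shared = int(round(overlap * n))
    n_excl = min((n - n_shared) // 2, max(2, int(round(0.15 * n))))
    perm = rng.permutation(n)
    shared = perm[:n_shared]
    a = np.concatenate([shared, perm[n_shared:n_shared + n_excl]])
    b = np.concatenate([shared, perm[n_shared + n_excl:n_shared + 2 * n_excl]])
    return np.sort(a), np.sort(b), np.sort(shared)


def benchmark_suite(config: BenchmarkConfig | None = None,
                    seed: int = 0) -> list[BenchmarkPair]:
    """Deterministic suite of easy and stress session pairs.

    Easy pairs: small tilt, high neuron overlap, no blur, mild background.
    Stress pairs: tilt >= 35 degrees, low overlap, strong blur, strong uneven
    background — the regime where intensity-based registration breaks down.
    The template session always uses the identity pose, so the ground-truth
    moving-to-template transform is the inverse of the moving session's pose.
    """
    cfg = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    pairs: list[BenchmarkPair] = []
    for stratum in ("easy", "stress"):
        for i in range(cfg.n_pairs_per_stratum):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            scene = generate_scene(cfg.n_neurons, cfg.frame_shape, seed=scene_seed)
            if stratum == "easy":
                tilt_deg = rng.uniform(*cfg.easy_tilt_deg)
                spin = math.radians(rng.uniform(*cfg.easy_spin_deg)) % (2 * math.pi)
                trans = rng.uniform(*cfg.easy_translation_px, size=2)
                overlap = cfg.easy_overlap
                blur = cfg.easy_blur_sigma
                bg = cfg.easy_background
                noise = cfg.easy_noise_sigma
            else:
                tilt_deg = rng.uniform(*cfg.stress_tilt_deg)
                spin = math.radians(rng.uniform(*cfg.stress_spin_deg)) % (2 * math.pi)
                trans = rng.uniform(*cfg.stress_translation_px, size=2)
                overlap = cfg.stress_overlap
                blur = rng.uniform(*cfg.stress_blur_sigma)
                bg = cfg.stress_background
                noise = cfg.stress_noise_sigma
            tilt = 1.0 / math.cos(math.radians(tilt_deg))
            phi = rng.uniform(0.0, math.pi)
            # conjugate the tilt axis: psi = spin - phi makes the net in-plane
            # rotation equal the camera spin, as for a physical tilt about an
            # axis at longitude phi
            pose = AffinePose(lambda_zoom=1.0, psi=(spin - phi) % (2 * math.pi),
                              tilt=tilt, phi=phi)
            sub_t, sub_m, shared = _split_subsets(cfg.n_neurons, overlap, rng)
            s_t = int(rng.integers(0, 2**31 - 1))
            s_m = int(rng.integers(0, 2**31 - 1))
            template = render_session(scene, pose=None, active_indices=sub_t,
                                      background_amplitude=cfg.easy_background,
                                      noise_sigma=cfg.easy_noise_sigma, seed=s_t)
            moving = render_session(scene, pose=pose, translation=trans,
                                    active_indices=sub_m, blur_sigma=blur,
                                    background_amplitude=bg, noise_sigma=noise,
                                    seed=s_m)
            true_mt = template.true_transform @ moving.true_transform.inverse()
            pairs.append(BenchmarkPair(
                pair_id=f"{stratum}-{i:02d}", stratum=stratum, scene=scene,
                template=template, moving=moving, true_transform=true_mt,
                shared_ids=shared))
    return pairs
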