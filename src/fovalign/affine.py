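"""Affine camera model and view simulation.

A planar affine map with positive determinant factors into camera parameters

    A = lambda * R(psi) @ diag(t, 1) @ R(phi)

where ``lambda`` is the camera zoom, ``psi`` the spin of the camera around its
optical axis, and ``(phi, theta)`` the longitude/latitude of the optical axis
relative to the frontal view, with tilt ``t = 1 / cos(theta)``.  Fully affine
invariant matching simulates a grid of (tilt, phi) views of each image, detects
keypoints on every simulated view, and maps them back into the original frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "AffinePose",
    "AffineTransform2D",
    "SimulatedView",
    "compose_affine",
    "decompose_affine",
    "sample_pose_grid",
    "simulate_view",
    "backproject_keypoints",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class AffinePose:
    """Camera-parameter decomposition (zoom, spin, tilt, longitude).

    ``theta = arccos(1/tilt)`` is the latitude angle implied by the tilt and is
    exposed as a derived property.  ``psi`` lives in ``[0, 2*pi)`` so that every
    positive-determinant linear map has a representation once ``phi`` is
    normalized into ``[0, pi)``.
    """

    lambda_zoom: float = 1.0
    psi: float = 0.0
    tilt: float = 1.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda_zoom > 0):
            raise ValueError(f"lambda_zoom must be positive, got {self.lambda_zoom}")
        if self.tilt < 1.0 - 1e-12:
            raise ValueError(f"tilt must be >= 1, got {self.tilt}")
        if not (0.0 <= self.phi < math.pi + 1e-12):
            raise ValueError(f"phi must lie in [0, pi), got {self.phi}")
        if not (0.0 <= self.psi < _TWO_PI + 1e-12):
            raise ValueError(f"psi must lie in [0, 2*pi), got {self.psi}")

    @property
    def theta(self) -> float:
        """Latitude angle in radians, ``arccos(1/tilt)``."""
        return math.acos(1.0 / self.tilt)


@dataclass(frozen=True)
class AffineTransform2D:
    """Planar affine map ``(x, y) -> (a x + b y + e, c x + d y + f)``.

    Coordinates follow the (x=column, y=row) convention with the origin at the
    top-left pixel center.
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    e: float = 0.0
    f: float = 0.0

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform2D":
        m = np.asarray(m, dtype=float)
        if m.shape == (3, 3):
            m = m[:2, :]
        if m.shape != (2, 3):
            raise ValueError(f"expected a 2x3 (or 3x3) matrix, got shape {m.shape}")
        return cls(a=m[0, 0], b=m[0, 1], e=m[0, 2], c=m[1, 0], d=m[1, 1], f=m[1, 2])

    @classmethod
    def from_linear(cls, linear: np.ndarray, translation=(0.0, 0.0)) -> "AffineTransform2D":
        linear = np.asarray(linear, dtype=float)
        return cls(a=linear[0, 0], b=linear[0, 1], c=linear[1, 0], d=linear[1, 1],
                   e=float(translation[0]), f=float(translation[1]))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """The 2x3 matrix ``[[a, b, e], [c, d, f]]``."""
        return np.array([[self.a, self.b, self.e], [self.c, self.d, self.f]], dtype=float)

    @property
    def homogeneous(self) -> np.ndarray:
        """The 3x3 homogeneous matrix."""
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    @property
    def linear(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.e, self.f], dtype=float)

    @property
    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return ``self o other`` (apply ``other`` first)."""
        return AffineTransform2D.from_matrix(self.homogeneous @ other.homogeneous)

    def __matmul__(self, other: "AffineTransform2D") -> "AffineTransform2D":
        return self.compose(other)

    def inverse(self) -> "AffineTransform2D":
        det = self.determinant
        if abs(det) < 1e-15:
            raise ValueError(f"transform is singular (determinant {det!r})")
        return AffineTransform2D.from_matrix(np.linalg.inv(self.homogeneous))

    def corner_displacement(self, other: "AffineTransform2D", shape) -> float:
        """Mean displacement (px) of the frame corners under self vs other.

        ``shape`` is the (rows, cols) image shape whose corners are compared.
        """
        h, w = shape[:2]
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        return float(np.linalg.norm(self.apply(corners) - other.apply(corners), axis=1).mean())


@dataclass(frozen=True)
class SimulatedView:
    """One affine-simulated view of an image.

    ``to_view`` maps original-frame (x, y) coordinates into the view frame,
    ``from_view`` is its exact inverse.  ``antialias_sigma`` records the
    Gaussian blur applied along the compressed axis before subsampling (the
    optical-blur kernel of the imaging model).
    """

    image: np.ndarray
    pose: AffinePose
    to_view: AffineTransform2D
    from_view: AffineTransform2D
    antialias_sigma: float = 0.0


def _rotation(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]], dtype=float)


def compose_affine(pose: AffinePose) -> AffineTransform2D:
    """Linear part ``lambda * R(psi) @ diag(t, 1) @ R(phi)`` (zero translation)."""
    m = pose.lambda_zoom * (_rotation(pose.psi) @ np.diag([pose.tilt, 1.0]) @ _rotation(pose.phi))
    return AffineTransform2D.from_linear(m)


def decompose_affine(m: AffineTransform2D | np.ndarray) -> AffinePose:
    """Recover (lambda, psi, tilt, phi) from a positive-determinant linear map.

    The tilt is the ratio of the two singular values of the linear part and the
    zoom is the smaller singular value; recomposition reproduces the input to
    ~1e-8.  Raises ``ValueError`` for non-positive determinants.
    """
    if isinstance(m, AffineTransform2D):
        lin = m.linear
    else:
        lin = np.asarray(m, dtype=float)
        if lin.shape == (2, 3):
            lin = lin[:, :2]
    det = float(np.linalg.det(lin))
    if det <= 0:
        raise ValueError(f"decomposition requires a positive determinant, got {det!r}")
    u, s, vt = np.linalg.svd(lin)
    # force both factors to be proper rotations (det +1)
    if np.linalg.det(u) < 0:
        u[:, 1] *= -1.0
        vt[1, :] *= -1.0
    lam = float(s[1])
    tilt = float(s[0] / s[1])
    if tilt < 1.0 + 1e-12:
        # isotropic: diag(t, 1) is the identity, fold everything into psi
        tilt = 1.0
        phi = 0.0
        r = u @ vt
        psi = math.atan2(r[1, 0], r[0, 0]) % _TWO_PI
    else:
        psi = math.atan2(u[1, 0], u[0, 0])
        phi = math.atan2(vt[1, 0], vt[0, 0])
        if phi < 0 or phi >= math.pi:
            # (psi, phi) -> (psi + pi, phi + pi) leaves the product unchanged
            phi = phi - math.pi if phi >= math.pi else phi + math.pi
            psi += math.pi
        psi %= _TWO_PI
    if psi >= _TWO_PI:
        psi = 0.0
    return AffinePose(lambda_zoom=lam, psi=psi, tilt=tilt, phi=phi)


def sample_pose_grid(max_tilt_index: int = 5) -> list[tuple[float, float]]:
    """The (tilt, phi) simulation grid, phi in degrees.

    Tilts follow the geometric series ``t_k = sqrt(2)**k``; for each tilt > 1
    the longitude is stepped by ``delta_phi = 72 / t`` degrees over ``[0, 180)``.
    The frontal view (t=1) contributes the single pose (1, 0).  Ordering is
    deterministic: increasing tilt, then increasing phi.
    """
    if not (0 <= max_tilt_index <= 8):
        raise ValueError(f"max_tilt_index must be in [0, 8], got {max_tilt_index}")
    grid: list[tuple[float, float]] = []
    for k in range(max_tilt_index + 1):
        t = 2.0 ** (k / 2)  # exact for even k, so m*dphi < 180 is evaluated exactly
        if k == 0:
            grid.append((1.0, 0.0))
            continue
        dphi = 72.0 / t
        m = 0
        while m * dphi < 180.0:
            grid.append((t, m * dphi))
            m += 1
    return grid


def _warp(image: np.ndarray, tform: AffineTransform2D, output_shape) -> np.ndarray:
    """Forward-warp ``image`` by ``tform`` with bilinear interpolation, zeros outside."""
    sk = sktransform.AffineTransform(matrix=tform.inverse().homogeneous)
    return sktransform.warp(image.astype(float), sk, output_shape=output_shape,
                            order=1, mode="constant", cval=0.0, preserve_range=True)


def simulate_view(image: np.ndarray, tilt: float, phi: float) -> SimulatedView:
    """Render one (tilt, phi) view: rotate by phi, anti-alias blur, subsample.

    Parameters
    ----------
    image : 2-D grayscale array.
    tilt : axis-compression factor ``t >= 1``.
    phi : longitude in degrees.

    The rotation expands the bounding box (no cropping); the tilt compresses the
    row (y) axis by ``t`` after a 1-D Gaussian blur of sigma
    ``0.8 * sqrt(t**2 - 1)`` along that axis.  ``to_view``/``from_view`` record
    the exact pixel mapping including the bounding-box translation.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("simulate_view expects a non-empty 2-D grayscale image")
    if tilt < 1.0 - 1e-12:
        raise ValueError(f"tilt must be >= 1, got {tilt}")
    phi_rad = math.radians(phi) % math.pi
    pose = AffinePose(tilt=max(tilt, 1.0), phi=phi_rad)
    h, w = img.shape

    if abs(tilt - 1.0) < 1e-12 and phi_rad < 1e-15:
        ident = AffineTransform2D.identity()
        return SimulatedView(image=img.copy(), pose=pose, to_view=ident,
                             from_view=ident, antialias_sigma=0.0)

    # rotation with bounding-box expansion
    rot = _rotation(phi_rad)
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    rc = corners @ rot.T
    offset = -rc.min(axis=0)
    t_rot = AffineTransform2D.from_linear(rot, translation=offset)
    out_w = int(math.ceil(rc[:, 0].max() - rc[:, 0].min())) + 1
    out_h = int(math.ceil(rc[:, 1].max() - rc[:, 1].min())) + 1
    rotated = _warp(img, t_rot, (out_h, out_w)) if phi_rad > 1e-15 else img.astype(float)
    if phi_rad <= 1e-15:
        t_rot = AffineTransform2D.identity()
        out_h, out_w = h, w

    # anti-alias blur along the to-be-compressed (row) axis, then subsample
    sigma = 0.8 * math.sqrt(max(tilt * tilt - 1.0, 0.0))
    if sigma > 0:
        rotated = ndimage.gaussian_filter1d(rotated, sigma=sigma, axis=0, mode="constant")
    t_scale = AffineTransform2D(a=1.0, b=0.0, c=0.0, d=1.0 / tilt, e=0.0, f=0.0)
    view_h = max(int(round(out_h / tilt)), 1)
    view = _warp(rotated, t_scale, (view_h, out_w)) if tilt > 1.0 + 1e-12 else rotated

    if min(view.shape) < 8:
        raise ValueError(
            f"simulated view degenerate: shape {view.shape} is below the 8 px minimum")
    to_view = t_scale @ t_rot
    return SimulatedView(image=view, pose=pose, to_view=to_view,
                         from_view=to_view.inverse(), antialias_sigma=sigma)


def backproject_keypoints(xy: np.ndarray, view: SimulatedView,
                          original_shape) -> tuple[np.ndarray, np.ndarray]:
    """Map view-frame (x, y) keypoints back into the original image frame.

    Returns ``(xy_original, keep_mask)`` where ``keep_mask`` flags keypoints
    whose backprojection lies inside the original image bounds; callers use the
    mask to subset descriptor payloads, which are never modified.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    h, w = original_shape[:2]
    if len(xy) == 0:
        return xy.reshape(0, 2), np.zeros(0, dtype=bool)
    back = view.from_view.apply(xy)
    keep = ((back[:, 0] >= 0) & (back[:, 0] <= w - 1)
            & (back[:, 1] >= 0) & (back[:, 1] <= h - 1))
    return back[keep], keep
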