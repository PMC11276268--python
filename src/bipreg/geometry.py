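"""Coordinate systems, transform models and the collinearity projection.

Object space is metric (mm); image measurements and the principal distance
are in pixels.  A camera is a pinhole with photogrammetric exterior
orientation (perspective-center position ``XC, YC, ZC`` and an
object-to-image rotation parameterized by the Euler sequence
``R3(kappa) @ R2(phi) @ R1(omega)``) plus interior orientation (principal
point ``xp, yp`` and principal distance ``c``) and an optional per-point
distortion-correction provider.

The projection model is the collinearity condition: the perspective
center, the image point and the object point lie on one line,

    x = xp - c * U / W + dx,    y = yp - c * V / W + dy,

with ``(U, V, W)`` the object point expressed in image space.  ``x``
grows with the image-space ``u`` axis and ``y`` with ``v``; mapping to
raster row order is an IO concern, not a geometry one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .exceptions import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "Pose",
    "QuatPose",
    "PointCloud",
    "CameraModel",
    "IdentityDistortion",
    "PolynomialDistortion",
    "GridDistortion",
    "euler_to_matrix",
    "matrix_to_euler",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_rotation_derivatives",
    "apply_rigid",
    "apply_scaled",
    "scale_about_centroid",
    "project",
    "backproject_at_depth",
    "triangulate",
]


# ---------------------------------------------------------------------------
# rotation parameterizations


def _check_finite(name: str, *values: float) -> None:
    if not np.all(np.isfinite(values)):
        raise InvalidArgumentError(f"{name} must be finite, got {values!r}")


def euler_to_matrix(omega: float, phi: float, kappa: float) -> np.ndarray:
    """Rotation matrix ``R3(kappa) @ R2(phi) @ R1(omega)`` (radians).

    ``R1, R2, R3`` are right-handed active rotations about the X, Y and Z
    axes with the column-vector convention.
    """
    _check_finite("Euler angles", omega, phi, kappa)
    so, co = np.sin(omega), np.cos(omega)
    sp, cp = np.sin(phi), np.cos(phi)
    sk, ck = np.sin(kappa), np.cos(kappa)
    r1 = np.array([[1.0, 0.0, 0.0], [0.0, co, -so], [0.0, so, co]])
    r2 = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    r3 = np.array([[ck, -sk, 0.0], [sk, ck, 0.0], [0.0, 0.0, 1.0]])
    return r3 @ r2 @ r1


def matrix_to_euler(m: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`euler_to_matrix`; returns ``(omega, phi, kappa)`` rad.

    At the gimbal-lock branch (``|cos(phi)| ~ 0``) omega is set to zero and
    the remaining freedom is absorbed into kappa.
    """
    m = np.asarray(m, dtype=float)
    sp = -m[2, 0]
    sp = min(1.0, max(-1.0, sp))
    phi = np.arcsin(sp)
    if abs(abs(sp) - 1.0) < 1e-12:
        omega = 0.0
        kappa = np.arctan2(-m[0, 1], m[1, 1])
    else:
        omega = np.arctan2(m[2, 1], m[2, 2])
        kappa = np.arctan2(m[1, 0], m[0, 0])
    return float(omega), float(phi), float(kappa)


def quat_to_matrix(q: Sequence[float]) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``(q0, q1, q2, q3)``, scalar first.

    The quaternion is renormalized internally; its norm must be within
    1e-6 of one (this is the working tolerance for the iteratively
    re-normalized estimate, not a statement about representable rotations).
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0 or not np.isfinite(n):
        raise InvalidArgumentError("zero or non-finite quaternion")
    if abs(n - 1.0) > 1e-6:
        raise InvalidArgumentError(f"quaternion norm {n} too far from 1")
    q0, q1, q2, q3 = q / n
    return np.array(
        [
            [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
        ]
    )


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Unit quaternion (scalar first, ``q0 >= 0``) of a rotation matrix."""
    q = _ScipyRotation.from_matrix(np.asarray(m, dtype=float)).as_quat()
    q = np.array([q[3], q[0], q[1], q[2]])  # scipy is (x, y, z, w)
    if q[0] < 0:
        q = -q
    return q


def quat_rotation_derivatives(q: Sequence[float]) -> list[np.ndarray]:
    """Analytic derivatives ``dR/dq_k`` of the 9-term quaternion expansion.

    Evaluated at the given (unnormalized) quaternion; used by the design
    matrix of the projection estimator.
    """
    q0, q1, q2, q3 = np.asarray(q, dtype=float)
    d0 = 2.0 * np.array([[q0, -q3, q2], [q3, q0, -q1], [-q2, q1, q0]])
    d1 = 2.0 * np.array([[q1, q2, q3], [q2, -q1, -q0], [q3, q0, -q1]])
    d2 = 2.0 * np.array([[-q2, q1, q0], [q1, q2, q3], [-q0, q3, -q2]])
    d3 = 2.0 * np.array([[-q3, -q0, q1], [q0, -q3, q2], [q1, q2, q3]])
    return [d0, d1, d2, d3]


# ---------------------------------------------------------------------------
# pose types


@dataclass(frozen=True)
class Pose:
    """Six-parameter rigid transform: translation (mm) + Euler rotation.

    Angles are stored in radians; use :meth:`from_degrees` /
    :meth:`angles_deg` at the interface.  The rotation matrix is the
    Euler factorization ``R3(kappa) @ R2(phi) @ R1(omega)`` and a point
    maps as ``M @ p + t``.
    """

    Xt: float = 0.0
    Yt: float = 0.0
    Zt: float = 0.0
    omega: float = 0.0
    phi: float = 0.0
    kappa: float = 0.0

    def __post_init__(self):
        _check_finite("Pose parameters", self.Xt, self.Yt, self.Zt, self.omega, self.phi, self.kappa)

    @classmethod
    def from_degrees(cls, Xt: float, Yt: float, Zt: float, omega_deg: float, phi_deg: float, kappa_deg: float) -> "Pose":
        return cls(Xt, Yt, Zt, np.deg2rad(omega_deg), np.deg2rad(phi_deg), np.deg2rad(kappa_deg))

    @classmethod
    def from_matrix(cls, m: np.ndarray, t: Sequence[float]) -> "Pose":
        omega, phi, kappa = matrix_to_euler(m)
        t = np.asarray(t, dtype=float)
        return cls(t[0], t[1], t[2], omega, phi, kappa)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.Xt, self.Yt, self.Zt])

    @property
    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.omega, self.phi, self.kappa)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.rad2deg([self.omega, self.phi, self.kappa])

    def compose(self, other: "Pose") -> "Pose":
        """Pose applying ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return Pose.from_matrix(m, t)

    def inverse(self) -> "Pose":
        m = self.matrix.T
        return Pose.from_matrix(m, -m @ self.translation)

    def to_quat_pose(self) -> "QuatPose":
        return QuatPose(self.Xt, self.Yt, self.Zt, matrix_to_quat(self.matrix))


@dataclass(frozen=True)
class QuatPose:
    """Rigid transform with the rotation as a unit quaternion (scalar first)."""

    Xt: float
    Yt: float
    Zt: float
    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,):
            raise InvalidArgumentError(f"quaternion must have 4 components, got {q.shape}")
        if np.linalg.norm(q) == 0 or not np.all(np.isfinite(q)):
            raise InvalidArgumentError("zero or non-finite quaternion")
        object.__setattr__(self, "q", q)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.Xt, self.Yt, self.Zt])

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.q / np.linalg.norm(self.q))

    def normalized(self) -> "QuatPose":
        return replace(self, q=self.q / np.linalg.norm(self.q))

    def to_pose(self) -> Pose:
        return Pose.from_matrix(self.matrix, self.translation)


# ---------------------------------------------------------------------------
# point clouds


@dataclass(frozen=True)
class PointCloud:
    """N x 3 object-space points (mm) with an optional fiducial-bead subset."""

    points: np.ndarray
    bead_indices: Optional[np.ndarray] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidArgumentError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] == 0:
            raise InvalidArgumentError("empty point cloud")
        if not np.all(np.isfinite(pts)):
            raise InvalidArgumentError("non-finite coordinates in point cloud")
        object.__setattr__(self, "points", pts)
        if self.bead_indices is not None:
            idx = np.asarray(self.bead_indices, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= pts.shape[0]):
                raise InvalidArgumentError("bead indices out of range")
            object.__setattr__(self, "bead_indices", idx)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def beads(self) -> np.ndarray:
        if self.bead_indices is None:
            raise InvalidArgumentError("point cloud carries no bead subset")
        return self.points[self.bead_indices]

    def bead_cloud(self) -> "PointCloud":
        return PointCloud(self.beads)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points, self.bead_indices)


def apply_rigid(pose: Pose | QuatPose, cloud: PointCloud) -> PointCloud:
    """Rigid-body transform of a cloud: each point maps to ``M @ p + t``."""
    m = pose.matrix
    return cloud.with_points(cloud.points @ m.T + pose.translation)


def scale_about_centroid(lam: float, cloud: PointCloud) -> PointCloud:
    """Scale a cloud about its own centroid: ``c + lam * (p - c)``.

    The centroid is invariant, so the scaling changes size but not
    location of the model.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise InvalidArgumentError(f"scale factor must be positive, got {lam}")
    c = cloud.centroid
    if lam == 1.0:
        return cloud
    return cloud.with_points(c + lam * (cloud.points - c))


def apply_scaled(pose: Pose | QuatPose, lam: float, cloud: PointCloud) -> PointCloud:
    """Scale-augmented non-rigid transform: centroid-invariant scaling by
    ``lam`` followed by the rigid transform.  ``lam == 1`` reduces to
    :func:`apply_rigid` exactly."""
    return apply_rigid(pose, scale_about_centroid(lam, cloud))


# ---------------------------------------------------------------------------
# distortion providers


class IdentityDistortion:
    """Zero correction everywhere (the default provider)."""

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        return np.zeros_like(x), np.zeros_like(x)


class PolynomialDistortion:
    """Bivariate-polynomial correction ``(dx, dy) = (Px(x, y), Py(x, y))``.

    ``coeffs_x`` / ``coeffs_y`` are 2-D coefficient arrays in the
    ``numpy.polynomial.polynomial.polyval2d`` layout.
    """

    def __init__(self, coeffs_x, coeffs_y):
        self.coeffs_x = np.atleast_2d(np.asarray(coeffs_x, dtype=float))
        self.coeffs_y = np.atleast_2d(np.asarray(coeffs_y, dtype=float))

    def __call__(self, x, y):
        from numpy.polynomial.polynomial import polyval2d

        return polyval2d(x, y, self.coeffs_x), polyval2d(x, y, self.coeffs_y)


class GridDistortion:
    """Lookup-grid correction with bilinear interpolation.

    ``x_nodes`` / ``y_nodes`` are strictly increasing sample coordinates and
    ``dx``/``dy`` tables are indexed ``[ix, iy]``.  Outside the grid the
    correction is extrapolated from the boundary cell.
    """

    def __init__(self, x_nodes, y_nodes, dx, dy):
        from scipy.interpolate import RegularGridInterpolator

        kw = dict(method="linear", bounds_error=False, fill_value=None)
        self._ix = RegularGridInterpolator((np.asarray(x_nodes, float), np.asarray(y_nodes, float)), np.asarray(dx, float), **kw)
        self._iy = RegularGridInterpolator((np.asarray(x_nodes, float), np.asarray(y_nodes, float)), np.asarray(dy, float), **kw)

    def __call__(self, x, y):
        pts = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)
        return self._ix(pts), self._iy(pts)


# ---------------------------------------------------------------------------
# camera model


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera of one lumped X-ray source/intensifier/camera chain.

    Exterior orientation: perspective center ``(XC, YC, ZC)`` in object
    space (mm) and object-to-image rotation angles (radians).  Interior
    orientation: principal point ``(xp, yp)`` and principal distance ``c``
    in pixels.  ``distortion`` maps image coordinates to additive
    correction terms ``(dx, dy)``.
    """

    XC: float
    YC: float
    ZC: float
    omega: float
    phi: float
    kappa: float
    xp: float
    yp: float
    c: float
    distortion: Callable = field(default_factory=IdentityDistortion)
    name: str = ""

    def __post_init__(self):
        _check_finite("Camera parameters", self.XC, self.YC, self.ZC, self.omega, self.phi, self.kappa, self.xp, self.yp, self.c)
        if self.c <= 0:
            raise InvalidArgumentError(f"principal distance must be positive, got {self.c}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.XC, self.YC, self.ZC])

    @property
    def rotation(self) -> np.ndarray:
        """Object-to-image rotation matrix ``M(kappa, phi, omega)``."""
        return euler_to_matrix(self.omega, self.phi, self.kappa)

    # -- projection chain ---------------------------------------------------

    def image_space(self, points: np.ndarray) -> np.ndarray:
        """``(U, V, W)`` image-space coordinates of object points (N x 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.position) @ self.rotation.T

    def depths(self, points: np.ndarray) -> np.ndarray:
        """Along-axis image-space depth ``W`` of object points."""
        return self.image_space(points)[:, 2]

    def ray(self, pt: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Viewing ray of an image point: ``(origin, direction)`` in object
        space.  The direction is chosen so that a point at signed depth
        ``W`` lies at ray parameter ``t = -W``."""
        x, y = float(pt[0]), float(pt[1])
        dx, dy = self.distortion(x, y)
        d_img = np.array([(x - self.xp - float(dx)) / self.c, (y - self.yp - float(dy)) / self.c, -1.0])
        return self.position, self.rotation.T @ d_img


def project(camera: CameraModel, points3d: PointCloud | np.ndarray) -> np.ndarray:
    """Collinearity projection of object points into one camera (N x 2, px).

    Raises :class:`DegenerateGeometryError` if any point lies in the
    principal plane (``W = 0``) or at the perspective center.
    """
    pts = points3d.points if isinstance(points3d, PointCloud) else np.atleast_2d(np.asarray(points3d, dtype=float))
    uvw = camera.image_space(pts)
    at_center = np.all(np.abs(pts - camera.position) < 1e-12, axis=1)
    if np.any(at_center):
        raise DegenerateGeometryError(
            f"point(s) {np.nonzero(at_center)[0].tolist()} coincide with the perspective center"
        )
    w = uvw[:, 2]
    bad = np.abs(w) < 1e-12
    if np.any(bad):
        raise DegenerateGeometryError(
            f"point(s) {np.nonzero(bad)[0].tolist()} lie in the principal plane (W = 0)"
        )
    x = camera.xp - camera.c * uvw[:, 0] / w
    y = camera.yp - camera.c * uvw[:, 1] / w
    ddx, ddy = camera.distortion(x, y)
    return np.stack([x + ddx, y + ddy], axis=1)


def backproject_at_depth(camera: CameraModel, pt: Sequence[float], reference3d: Sequence[float]) -> np.ndarray:
    """Lift an image point to 3D along its viewing ray, at the image-space
    depth of ``reference3d``.

    This is the construction behind the back-projection precision metric:
    a matched 2D edge point is assigned the depth of its matching model
    point.
    """
    ref = np.asarray(reference3d, dtype=float)
    w_ref = float(camera.depths(ref[None, :])[0])
    if abs(w_ref) < 1e-12:
        raise DegenerateGeometryError("reference point lies in the principal plane")
    origin, direction = camera.ray(pt)
    # along the ray W(t) = -t, so W = w_ref at t = -w_ref
    return origin + (-w_ref) * direction


def triangulate(cam1: CameraModel, cam2: CameraModel, pt1: Sequence[float], pt2: Sequence[float]) -> np.ndarray:
    """Two-ray spatial intersection: midpoint of the common perpendicular.

    Solves the 2 x 2 least-squares system for the ray parameters
    minimizing the squared distance between points on the two viewing
    rays, and returns the midpoint of the connecting segment.
    """
    o1, d1 = cam1.ray(pt1)
    o2, d2 = cam2.ray(pt2)
    a11 = d1 @ d1
    a12 = -(d1 @ d2)
    a22 = d2 @ d2
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-12 * a11 * a22:
        raise DegenerateGeometryError("viewing rays are parallel; triangulation undefined")
    b = o2 - o1
    t1 = (a22 * (d1 @ b) + (-a12) * (-(d2 @ b))) / det
    t2 = (a11 * (-(d2 @ b)) + (-a12) * (d1 @ b)) / det
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return 0.5 * (p1 + p2)
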