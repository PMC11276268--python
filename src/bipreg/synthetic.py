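"""Synthetic study fixtures: bone-like phantoms, a convergent two-camera
rig, rendered marker/silhouette radiographs and simulated motion trials.

The generators emulate the components of a biplanar videoradiography
experiment: a CT/MRI-segmented bone surface with a handful of implanted
steel beads, two calibrated X-ray imaging chains converging on the
measurement volume, and turntable-style trials in which the object
rotates about the vertical axis between epochs.  Everything is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InvalidArgumentError
from .geometry import (
    CameraModel,
    PointCloud,
    Pose,
    apply_rigid,
    matrix_to_euler,
    project,
)

__all__ = [
    "RigSpec",
    "TrialSpec",
    "TrialData",
    "make_phantom",
    "make_rig",
    "render_marker_image",
    "render_silhouette_image",
    "simulate_trial",
]

BEAD_DIAMETER_MM = 3.0  # steel fiducial beads glued to the bone surface


# ---------------------------------------------------------------------------
# phantom


def _ellipsoid_points(rng, n, semi_axes, center):
    """Uniform-direction samples on an ellipsoid surface."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(semi_axes) + np.asarray(center)


# the composite shape: an elongated shaft plus two condyle-like lobes and
# one small off-axis tubercle that breaks every 180-degree flip symmetry
_SHAPES = {
    "femur": dict(
        shaft=((60.0, 22.0, 18.0), (0.0, 0.0, 0.0)),
        lobes=[
            (16.0, (52.0, 14.0, -6.0)),
            (16.0, (52.0, -14.0, -6.0)),
            (9.0, (-48.0, 10.0, 12.0)),
        ],
    ),
    "tibia": dict(
        shaft=((55.0, 18.0, 15.0), (0.0, 0.0, 0.0)),
        lobes=[
            (14.0, (-48.0, 12.0, 5.0)),
            (14.0, (-48.0, -10.0, -5.0)),
            (8.0, (42.0, -8.0, 10.0)),
        ],
    ),
}


def make_phantom(
    n_surface_points: int = 1500,
    n_beads: int = 7,
    shape: str = "femur",
    seed: int = 0,
    min_bead_separation: float = 25.0,
) -> PointCloud:
    """Bone-like surface point cloud with fiducial beads on the surface.

    The surface is the union of an elongated ellipsoidal shaft, two
    condyle-like spherical lobes at one end and a small off-axis lobe at
    the other, centered near the origin.  The shape is deliberately
    asymmetric so that no 180-degree flip maps it onto itself and all six
    pose parameters are identifiable.  Beads are drawn from the surface
    points with a minimum mutual separation (default 25 mm) so their
    projections stay well separated.
    """
    if n_beads < 3:
        raise InvalidArgumentError("need at least 3 beads for registration")
    if shape not in _SHAPES:
        raise InvalidArgumentError(f"unknown phantom shape {shape!r}; options: {sorted(_SHAPES)}")
    spec = _SHAPES[shape]
    rng = np.random.default_rng(seed)
    shaft_axes, shaft_c = spec["shaft"]
    lobes = spec["lobes"]

    parts = [_ellipsoid_points(rng, n_surface_points, shaft_axes, shaft_c)]
    n_lobe = max(60, n_surface_points // 6)
    for r, c in lobes:
        parts.append(_ellipsoid_points(rng, n_lobe, (r, r, r), c))
    pts = np.vstack(parts)
    # keep only the outer union surface: drop samples buried inside another part
    pts = pts[~_buried(pts, shaft_axes, shaft_c, lobes)]

    order = rng.permutation(len(pts))
    bead_idx = []
    for i in order:
        if all(np.linalg.norm(pts[i] - pts[j]) >= min_bead_separation for j in bead_idx):
            bead_idx.append(i)
        if len(bead_idx) == n_beads:
            break
    if len(bead_idx) < n_beads:
        raise InvalidArgumentError(
            f"cannot place {n_beads} beads with {min_bead_separation} mm separation on this surface"
        )
    return PointCloud(pts, np.array(sorted(bead_idx)))


def _buried(points, shaft_axes, shaft_c, lobes):
    """True where a sample lies strictly inside a component other than its own."""
    n = len(points)
    buried = np.zeros(n, dtype=bool)
    in_shaft = np.sum(((points - np.asarray(shaft_c)) / np.asarray(shaft_axes)) ** 2, axis=1) < 0.998
    in_lobe = [np.sum((points - np.asarray(c)) ** 2, axis=1) < (0.999 * r) ** 2 for r, c in lobes]
    # shaft samples come first; a point is buried if inside any *other* part
    buried |= in_shaft
    for m in in_lobe:
        buried |= m
    # points exactly on their own surface are not "inside" it thanks to the
    # strict margins above, so the union of the masks is what we want
    return buried


# ---------------------------------------------------------------------------
# rig


@dataclass(frozen=True)
class RigSpec:
    """Geometry of the convergent two-camera imaging rig.

    ``inter_axis_angle_deg`` is the angle between the two optical axes at
    their intersection (the origin).  ``source_to_object_mm`` is the
    perspective-center distance to the origin.  The principal distance is
    in pixels of the final image.
    """

    inter_axis_angle_deg: float = 60.0
    source_to_object_mm: float = 1000.0
    principal_distance_px: float = 2800.0
    image_size: tuple[int, int] = (1008, 1008)

    def __post_init__(self):
        if not 0.0 < self.inter_axis_angle_deg < 180.0:
            raise InvalidArgumentError("inter-axis angle must be in (0, 180) degrees")
        if min(self.image_size) <= 0 or self.source_to_object_mm <= 0 or self.principal_distance_px <= 0:
            raise InvalidArgumentError("rig dimensions must be positive")


def _camera_at(position: np.ndarray, spec: RigSpec, name: str, up=(0.0, 1.0, 0.0)) -> CameraModel:
    """Camera at ``position`` looking at the origin, image u-axis horizontal."""
    w = position / np.linalg.norm(position)  # points scene -> camera
    up = np.asarray(up, dtype=float)
    u = np.cross(up, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    m = np.vstack([u, v, w])  # object-to-image rotation
    omega, phi, kappa = matrix_to_euler(m)
    w_img, h_img = spec.image_size
    return CameraModel(
        XC=position[0],
        YC=position[1],
        ZC=position[2],
        omega=omega,
        phi=phi,
        kappa=kappa,
        xp=(w_img - 1) / 2.0,
        yp=(h_img - 1) / 2.0,
        c=spec.principal_distance_px,
        name=name,
    )


def make_rig(spec: RigSpec = RigSpec(), check_cloud: Optional[PointCloud] = None) -> tuple[CameraModel, CameraModel]:
    """Two cameras converging on the origin at the spec'd inter-axis angle.

    Cameras sit in the X-Z plane (Y is the vertical axis of the scene) at
    azimuths of half the inter-axis angle either side of the +Z direction.
    If ``check_cloud`` is given, its projection must fall inside the image
    bounds in both cameras.
    """
    half = np.deg2rad(spec.inter_axis_angle_deg / 2.0)
    d = spec.source_to_object_mm
    c1 = _camera_at(np.array([d * np.sin(half), 0.0, d * np.cos(half)]), spec, "cam1")
    c2 = _camera_at(np.array([-d * np.sin(half), 0.0, d * np.cos(half)]), spec, "cam2")
    if check_cloud is not None:
        w_img, h_img = spec.image_size
        for cam in (c1, c2):
            xy = project(cam, check_cloud)
            if xy.min() < 0 or xy[:, 0].max() >= w_img or xy[:, 1].max() >= h_img:
                raise InvalidArgumentError(
                    f"cloud projects outside the {w_img}x{h_img} frame of {cam.name}"
                )
    return c1, c2


# ---------------------------------------------------------------------------
# rendering helpers


def _downsample(img: np.ndarray, s: int) -> np.ndarray:
    h, w = img.shape
    return img.reshape(h // s, s, w // s, s).mean(axis=(1, 3))


def _background(rng, shape, level=0.78, texture=0.01):
    """Bright, gently textured background (smooth low-frequency field)."""
    coarse = rng.normal(0.0, 1.0, (8, 8))
    from scipy.ndimage import zoom, gaussian_filter

    tex = zoom(coarse, (shape[0] / 8, shape[1] / 8), order=3)
    tex = gaussian_filter(tex, 4)
    return np.clip(level + texture * tex, 0.0, 1.0)


def render_marker_image(
    camera: CameraModel,
    cloud: PointCloud,
    pose: Pose,
    bead_radius_mm: float = BEAD_DIAMETER_MM / 2.0,
    background_level: float = 0.78,
    background_texture: float = 0.01,
    noise_sigma: float = 0.0,
    seed: int = 0,
    low_intensity_region: Optional[tuple[float, float, float, float]] = None,
    supersample: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the bead subset of ``cloud`` at ``pose`` into one radiograph.

    Beads appear as dark elliptical footprints (projected spheres) on a
    textured bright background.  ``low_intensity_region`` is an optional
    ``(cx, cy, radius, factor)`` circular region whose intensity (and
    therefore local bead contrast) is multiplied by ``factor`` -- the
    classic under-exposed corner in which markers evade edge detection
    until the image is enhanced.

    Returns ``(image, true_centers)`` with the image float in [0, 1] and
    the analytically projected bead centers in px.  Bead footprints are
    drawn with ``supersample`` x antialiasing on local patches.
    """
    rng = np.random.default_rng(seed)
    w_img, h_img = int(camera.xp * 2 + 1), int(camera.yp * 2 + 1)
    moved = apply_rigid(pose, cloud.bead_cloud())
    centers = project(camera, moved)
    depth = np.abs(camera.depths(moved.points))
    radii_px = camera.c * bead_radius_mm / depth

    img = _background(rng, (h_img, w_img), background_level, background_texture)
    if low_intensity_region is not None:
        cx, cy, rad, factor = low_intensity_region
        yy, xx = np.mgrid[0:h_img, 0:w_img]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < rad**2
        img[mask] *= factor

    s = int(supersample)
    transmission = np.ones((h_img, w_img))
    for (cx, cy), r in zip(centers, radii_px):
        pad = int(np.ceil(r)) + 2
        x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
        y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
        x0, x1 = max(x0, 0), min(x1, w_img)
        y0, y1 = max(y0, 0), min(y1, h_img)
        if x0 >= x1 or y0 >= y1:
            continue
        ys = (np.arange(y0 * s, y1 * s) + 0.5) / s - 0.5
        xs = (np.arange(x0 * s, x1 * s) + 0.5) / s - 0.5
        dist2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
        patch = np.where(dist2 < r * r, 0.12, 1.0)
        transmission[y0:y1, x0:x1] = np.minimum(
            transmission[y0:y1, x0:x1], _downsample(patch, s)
        )
    img = img * transmission
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), centers


def render_silhouette_image(
    camera: CameraModel,
    cloud: PointCloud,
    pose: Pose,
    edge_blur_sigma: float = 1.5,
    inward_offset_px: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    closing_radius_px: Optional[int] = None,
    interior_level: float = 0.30,
    background_level: float = 0.78,
) -> np.ndarray:
    """Render the filled projected silhouette of the model at ``pose``.

    The projected point cloud is rasterized, morphologically closed into a
    filled silhouette (closing radius defaults to twice the median
    nearest-neighbor spacing of the projection, enough to bridge the
    sampling gaps), optionally eroded by ``inward_offset_px`` to place
    the apparent boundary systematically inside the true one (emulating
    the inward bias of heavily smoothed edge detection), then blurred and
    corrupted with Gaussian intensity noise.
    """
    from scipy.ndimage import (
        binary_closing,
        binary_erosion,
        binary_fill_holes,
        gaussian_filter,
    )
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    w_img, h_img = int(camera.xp * 2 + 1), int(camera.yp * 2 + 1)
    xy = project(camera, apply_rigid(pose, cloud))
    cols = np.clip(np.round(xy[:, 0]).astype(int), 0, w_img - 1)
    rows = np.clip(np.round(xy[:, 1]).astype(int), 0, h_img - 1)
    occ = np.zeros((h_img, w_img), dtype=bool)
    occ[rows, cols] = True

    if closing_radius_px is None:
        nn, _ = cKDTree(xy).query(xy, k=2)
        closing_radius_px = max(3, int(np.ceil(2.0 * float(np.median(nn[:, 1])))))
    yy, xx = np.mgrid[-closing_radius_px : closing_radius_px + 1, -closing_radius_px : closing_radius_px + 1]
    disk = xx**2 + yy**2 <= closing_radius_px**2
    sil = binary_fill_holes(binary_closing(occ, structure=disk, border_value=0))
    n_off = int(round(inward_offset_px))
    if n_off > 0:
        yo, xo = np.mgrid[-n_off : n_off + 1, -n_off : n_off + 1]
        sil = binary_erosion(sil, structure=xo**2 + yo**2 <= n_off**2)

    img = _background(rng, (h_img, w_img), background_level)
    img[sil] = interior_level
    img = gaussian_filter(img, edge_blur_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# trials


@dataclass(frozen=True)
class TrialSpec:
    """One simulated motion trial.

    The default motion is an incremental rotation about the vertical
    (Y) axis per epoch, emulating a turntable acquisition; translation
    drift can be added per epoch.  ``noise_sigma_px`` is i.i.d. Gaussian
    noise added to the extracted 2D bead coordinates (the coordinate-level
    injection point; pixel-intensity noise lives in the renderers).
    """

    n_epochs: int = 10
    rotation_increment_deg: float = 2.0
    translation_drift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma_px: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs < 1:
            raise InvalidArgumentError("a trial needs at least one epoch")
        if self.noise_sigma_px < 0:
            raise InvalidArgumentError("noise sigma must be non-negative")


@dataclass
class TrialData:
    """Simulated trial: ground truth poses and per-camera noisy bead tracks."""

    spec: TrialSpec
    true_poses: list[Pose]
    bead_tracks: list[list[np.ndarray]]  # [epoch][camera] -> (n_beads, 2) px
    true_projections: list[list[np.ndarray]] = field(default_factory=list)


def simulate_trial(spec: TrialSpec, phantom: PointCloud, rig: tuple[CameraModel, CameraModel]) -> TrialData:
    """Generate ground-truth poses and noisy 2D bead tracks for a trial."""
    rng = np.random.default_rng(spec.seed)
    poses, tracks, clean = [], [], []
    beads = phantom.bead_cloud()
    for k in range(spec.n_epochs):
        drift = np.asarray(spec.translation_drift_mm) * k
        pose = Pose.from_degrees(drift[0], drift[1], drift[2], 0.0, spec.rotation_increment_deg * k, 0.0)
        moved = apply_rigid(pose, beads)
        per_cam_clean = [project(cam, moved) for cam in rig]
        per_cam = [xy + rng.normal(0.0, spec.noise_sigma_px, xy.shape) for xy in per_cam_clean]
        poses.append(pose)
        tracks.append(per_cam)
        clean.append(per_cam_clean)
    return TrialData(spec=spec, true_poses=poses, bead_tracks=tracks, true_projections=clean)
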