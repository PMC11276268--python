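"""Feature-based (model-based) registration front end.

When no beads are implanted, the pose is recovered from the bone
silhouette itself: a bank of Canny detectors with staggered smoothing
scales and hysteresis thresholds extracts robust edge points from each
radiograph (single detectors miss segments of the low-contrast bone
boundary), the overlaid responses are thinned to one-pixel chains, and
these edge points form the master data.  The slave data are the outline
points of the projected model cloud; nearest-point one-to-one matching
links the two and the same quaternion-constrained least squares as the
marker pipeline estimates the pose (rigid, or with a centroid-invariant
scale factor absorbing systematic inward edge offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from skimage import morphology

from .estimation import (
    CameraCorrespondences,
    CorrespondenceSet,
    RegistrationOptions,
    RegistrationResult,
    _solve_pose,
    reject_outliers,
)
from .exceptions import (
    DegenerateDataError,
    DegenerateGeometryError,
    InvalidArgumentError,
)
from .geometry import (
    CameraModel,
    PointCloud,
    Pose,
    QuatPose,
    backproject_at_depth,
    project,
    scale_about_centroid,
)
from .targets import canny_edges

__all__ = [
    "EdgePointSet",
    "OutlinePointSet",
    "EdgeBankParams",
    "default_threshold_pairs",
    "multi_canny_bank",
    "thin_edges",
    "project_outline",
    "match_one_to_one",
    "register_model_based",
    "register_edges",
    "PrecisionReport",
    "precision_rms_3d",
    "render_overlay",
]


@dataclass
class EdgePointSet:
    """Edge points (x, y in px) with the id of the bank filter that first
    produced each point."""

    points: np.ndarray  # (M, 2)
    provenance: np.ndarray  # (M,) filter index

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.provenance = np.asarray(self.provenance, dtype=int)

    def __len__(self):
        return len(self.points)


@dataclass
class OutlinePointSet:
    """Boundary subset of the projected model points; every outline point
    carries the index of the 3D model point it came from."""

    points: np.ndarray  # (K, 2) px
    model_idx: np.ndarray  # (K,)

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# edge bank


def default_threshold_pairs(n: int = 5, loose=(0.05, 0.12), strict=(0.15, 0.35)) -> list[tuple[float, float]]:
    """Hysteresis pairs spaced geometrically from loose to strict."""
    lo = np.geomspace(loose[0], strict[0], n)
    hi = np.geomspace(loose[1], strict[1], n)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


@dataclass
class EdgeBankParams:
    """The Canny bank: every (sigma, threshold-pair) combination is one
    filter.  The default 5 x 5 = 25-filter bank spans smoothing scales
    4-8 px, wide enough to pick up both crisp and diffuse stretches of
    the bone boundary."""

    sigmas: tuple = (4.0, 5.0, 6.0, 7.0, 8.0)
    threshold_pairs: Optional[list] = None
    thin: bool = True

    def pairs(self) -> list[tuple[float, float]]:
        return self.threshold_pairs if self.threshold_pairs is not None else default_threshold_pairs()


def multi_canny_bank(image: np.ndarray, sigmas: Sequence[float], threshold_pairs: Sequence[tuple[float, float]]) -> EdgePointSet:
    """Union of the edge points of every filter in the bank.

    Duplicate pixels keep the provenance of the first (lowest-index)
    filter that produced them.  Filter index enumerates sigma-major,
    i.e. ``filter = i_sigma * len(threshold_pairs) + i_pair``.
    """
    if len(sigmas) == 0 or len(threshold_pairs) == 0:
        raise InvalidArgumentError("edge bank must contain at least one filter")
    seen = np.zeros(np.asarray(image).shape, dtype=bool)
    prov = np.full(np.asarray(image).shape, -1, dtype=int)
    fid = 0
    for s in sigmas:
        for lo, hi in threshold_pairs:
            em = canny_edges(image, s, lo, hi)
            new = em & ~seen
            prov[new] = fid
            seen |= em
            fid += 1
    rows, cols = np.nonzero(seen)
    return EdgePointSet(np.stack([cols, rows], axis=1).astype(float), prov[rows, cols])


def thin_edges(edges: EdgePointSet, image_shape: Optional[tuple[int, int]] = None) -> EdgePointSet:
    """Morphological thinning of the overlaid edge map to one-pixel chains.

    Multiple filter responses to the same physical edge collapse onto a
    single centerline; thinning never creates a pixel that was absent
    from the input map, so provenance is carried through unchanged.
    Idempotent.
    """
    if len(edges) == 0:
        return edges
    pts = edges.points.astype(int)
    if image_shape is None:
        image_shape = (pts[:, 1].max() + 2, pts[:, 0].max() + 2)
    bin_map = np.zeros(image_shape, dtype=bool)
    bin_map[pts[:, 1], pts[:, 0]] = True
    prov = np.full(image_shape, -1, dtype=int)
    prov[pts[:, 1], pts[:, 0]] = edges.provenance
    thin = morphology.thin(bin_map)
    rows, cols = np.nonzero(thin)
    return EdgePointSet(np.stack([cols, rows], axis=1).astype(float), prov[rows, cols])


# ---------------------------------------------------------------------------
# projected outline


def project_outline(
    camera: CameraModel,
    pose: Pose | QuatPose,
    lam: float,
    cloud: PointCloud,
    cell_size: Optional[float] = None,
) -> OutlinePointSet:
    """Outline points of the projected model cloud.

    The projected points are binned on an occupancy grid (cell size
    defaulting to the median nearest-neighbor spacing of the projection);
    cells with an empty 4-neighbor are boundary cells, and each boundary
    cell is represented by its most outward member point (outward =
    direction of the empty neighborhood), keeping its 3D model index.
    Choosing the extreme rather than the central member keeps the
    outline on the boundary of the projected set instead of half a cell
    inside it.
    """
    from scipy.spatial import cKDTree

    moved = scale_about_centroid(lam, cloud)
    xy = project(camera, moved.points @ pose.matrix.T + pose.translation)
    if len(xy) < 3:
        raise DegenerateGeometryError("need at least 3 projected points")
    d, _ = cKDTree(xy).query(xy, k=2)
    median_nn = max(float(np.median(d[:, 1])), 1e-6)
    if cell_size is None:
        cell_size = median_nn
    # uniform-coverage spacing: how far apart points would sit if spread
    # evenly over the bounding box; rim-dense projections (a sphere) have
    # interiors this sparse, and the closing radius must bridge them
    extent = xy.max(axis=0) - xy.min(axis=0)
    coverage = 1.5 * float(np.sqrt(max(extent[0] * extent[1], 1e-12) / len(xy)))
    close_r = max(1, int(np.ceil(coverage / cell_size)))
    span = xy.min(axis=0)
    ij = np.floor((xy - span) / cell_size).astype(int)
    nx, ny = ij[:, 0].max() + 1, ij[:, 1].max() + 1
    if max(nx, ny) < 2:
        raise DegenerateGeometryError("projected cloud degenerate at this cell size")
    occ = np.zeros((nx, ny), dtype=bool)
    occ[ij[:, 0], ij[:, 1]] = True
    # sparse sampling leaves interior holes that would masquerade as
    # boundary cells; close and fill the grid before the boundary test.
    # The occupied region abuts the array edge by construction, so the
    # closing must run on a padded copy or its zero border would erode
    # the outermost ring of cells.
    from scipy.ndimage import binary_closing, binary_fill_holes

    yy, xx = np.mgrid[-close_r : close_r + 1, -close_r : close_r + 1]
    disk = xx**2 + yy**2 <= close_r**2
    pad_n = close_r + 1
    occ_padded = np.pad(occ, pad_n)
    filled = binary_fill_holes(binary_closing(occ_padded, structure=disk))[pad_n:-pad_n, pad_n:-pad_n]
    pad = np.pad(filled, 1, constant_values=False)
    nb = pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    boundary = occ & filled & ~nb  # occupied cell with an empty 4-neighbor
    sel_idx = []
    cell_of = ij[:, 0] * ny + ij[:, 1]
    order = np.argsort(cell_of, kind="stable")
    bounds = np.searchsorted(cell_of[order], np.arange(nx * ny + 1))
    bi, bj = np.nonzero(boundary)
    occ_pad = np.pad(filled, 1, constant_values=False).astype(float)
    for i, j in zip(bi, bj):
        members = order[bounds[i * ny + j] : bounds[i * ny + j + 1]]
        if len(members) == 0:
            continue
        # outward direction: away from the occupied side of the 3x3 block
        block = occ_pad[i : i + 3, j : j + 3]
        gx = block[2, :].sum() - block[0, :].sum()
        gy = block[:, 2].sum() - block[:, 0].sum()
        n = np.hypot(gx, gy)
        if n < 1e-12:
            center = span + (np.array([i, j]) + 0.5) * cell_size
            k = members[np.argmin(np.sum((xy[members] - center) ** 2, axis=1))]
        else:
            d = -np.array([gx, gy]) / n  # away from occupied mass
            k = members[np.argmax(xy[members] @ d)]
        sel_idx.append(k)
    sel_idx = np.array(sorted(set(sel_idx)))
    return OutlinePointSet(xy[sel_idx], sel_idx)


def match_one_to_one(edges: EdgePointSet | np.ndarray, outline: OutlinePointSet) -> CameraCorrespondences:
    """One-to-one edge-to-outline correspondence by the two-pass rule.

    Every edge point claims its nearest outline point; an outline point
    claimed several times keeps only the closest claim.  The result is
    injective in the outline points; master coordinates are the edge
    points, model indices those of the matched outline points.
    """
    from scipy.spatial import cKDTree

    pts = edges.points if isinstance(edges, EdgePointSet) else np.atleast_2d(np.asarray(edges, dtype=float))
    if len(pts) == 0 or len(outline) == 0:
        raise InvalidArgumentError("matching requires non-empty edge and outline sets")
    dist, nearest = cKDTree(outline.points).query(pts)
    keep: dict[int, tuple[int, float]] = {}
    for ei, (oi, d) in enumerate(zip(nearest, dist)):
        if oi not in keep or d < keep[oi][1]:
            keep[oi] = (ei, d)
    pairs = sorted((ei, oi) for oi, (ei, _) in keep.items())
    rows = np.array([p[0] for p in pairs], dtype=int)
    master = pts[rows]
    model_idx = outline.model_idx[[p[1] for p in pairs]]
    return CameraCorrespondences(master, model_idx, master_rows=rows)


# ---------------------------------------------------------------------------
# driver


def register_model_based(
    images: Sequence[np.ndarray],
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    init: Pose | QuatPose,
    opts: Optional[RegistrationOptions] = None,
    bank: Optional[EdgeBankParams] = None,
    cell_size: Optional[float] = None,
    multiscale: bool = True,
) -> RegistrationResult:
    """Full model-based registration of an image pair.

    The edge bank runs once per image (edges do not depend on the pose);
    the loop then alternates projected-outline extraction, one-to-one
    matching, the constrained least-squares solve and 3-sigma rejection
    until the correspondence stabilizes and the update is below
    tolerance.  With ``multiscale`` (default) a short coarse pass with a
    4x outline cell smooths the correspondence landscape before the fine
    pass -- discrete outline re-sampling otherwise traps starts a few
    mm / degrees away in sub-pixel local minima.
    """
    opts = opts or RegistrationOptions(max_outer=80)
    bank = bank or EdgeBankParams()
    if len(images) != len(cameras):
        raise InvalidArgumentError("one image per camera required")
    edge_sets = []
    for img in images:
        es = multi_canny_bank(img, bank.sigmas, bank.pairs())
        if bank.thin:
            es = thin_edges(es, np.asarray(img).shape)
        edge_sets.append(es)
    start = init
    if multiscale:
        from scipy.spatial import cKDTree

        pose0 = init if isinstance(init, Pose) else init.to_pose()
        xy = project(cameras[0], cloud.points @ pose0.matrix.T + pose0.translation)
        d, _ = cKDTree(xy).query(xy, k=2)
        base_cell = cell_size if cell_size is not None else max(float(np.median(d[:, 1])), 1e-6)
        coarse = register_edges(
            edge_sets, cloud, cameras, init, replace(opts, max_outer=15), cell_size=4.0 * base_cell
        )
        start = coarse.pose
    return register_edges(edge_sets, cloud, cameras, start, opts, cell_size)


def register_edges(
    edge_sets: Sequence[EdgePointSet],
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    init: Pose | QuatPose,
    opts: Optional[RegistrationOptions] = None,
    cell_size: Optional[float] = None,
) -> RegistrationResult:
    """Model-based registration from pre-extracted edge point sets."""
    opts = opts or RegistrationOptions()
    q_pose = init.to_quat_pose() if isinstance(init, Pose) else init.normalized()
    fixed_scale = opts.mode == "scaled" and opts.fixed_lam is not None
    if fixed_scale:
        work_cloud = scale_about_centroid(opts.fixed_lam, cloud)
        work_opts = replace(opts, mode="rigid", fixed_lam=None)
    else:
        work_cloud, work_opts = cloud, opts
    lam = 1.0 if work_opts.mode == "scaled" else None

    prev_state = None
    total_iters = 0
    corr = None
    last_l = None
    converged = False
    message = ""
    n_excluded = 0
    # rejections are persistent across re-matching rounds: an edge point
    # flagged as a mismatch stays excluded, so the loop has a fixed point
    excluded = [np.zeros(len(es), dtype=bool) for es in edge_sets]
    for outer in range(1, opts.max_outer + 1):
        per_cam = []
        for cam, es, excl in zip(cameras, edge_sets, excluded):
            outline = project_outline(cam, q_pose, lam if lam is not None else 1.0, work_cloud, cell_size)
            cc = match_one_to_one(es, outline)
            keep = ~excl[cc.master_rows]
            per_cam.append(
                CameraCorrespondences(cc.master_xy[keep], cc.model_idx[keep], master_rows=cc.master_rows[keep])
            )
        corr = CorrespondenceSet(per_cam)

        q_pose, lam, l, iters, ok = _solve_pose(q_pose, lam, work_cloud, cameras, corr, work_opts)
        total_iters += iters
        if opts.reject and outer <= opts.reject_rounds and corr.n_active > 2:
            try:
                corr2 = reject_outliers(corr, l, opts.outlier_k)
            except DegenerateDataError:
                corr2 = corr
            if corr2.n_rejected > corr.n_rejected:
                for cc, excl in zip(corr2.per_camera, excluded):
                    excl[cc.master_rows[~cc.active]] = True
                corr = corr2
                q_pose, lam, l, iters, ok = _solve_pose(q_pose, lam, work_cloud, cameras, corr, work_opts)
                total_iters += iters
        last_l = l
        n_excluded = int(sum(e.sum() for e in excluded))

        # outer convergence: re-matching no longer moves the parameters
        state = np.concatenate([q_pose.translation, q_pose.q, [lam if lam is not None else 1.0]])
        if ok and prev_state is not None and np.max(np.abs(state - prev_state)) < opts.outer_tol:
            converged = True
            break
        prev_state = state
    else:
        message = f"correspondence still changing after {opts.max_outer} outer iterations"

    from .estimation import _covariance_report

    out_lam = opts.fixed_lam if fixed_scale else lam
    sigmas, lam_sigma, rms = _covariance_report(q_pose, lam, work_cloud, cameras, corr, work_opts)
    return RegistrationResult(
        pose=q_pose.to_pose(),
        lam=out_lam if opts.mode == "scaled" else None,
        rms_2d=rms,
        param_sigmas=sigmas,
        lam_sigma=lam_sigma,
        iterations=total_iters,
        n_rejected=max(corr.n_rejected, n_excluded),
        converged=converged,
        correspondences=corr,
        objective=float(last_l @ last_l),
        message=message,
    )


# ---------------------------------------------------------------------------
# precision metric


@dataclass
class PrecisionReport:
    """Back-projection precision: RMS 3D distance between registered model
    points and their matched edge points lifted to the model point's
    depth, overall and per object-space axis."""

    rms_distance: float
    rms_axis: np.ndarray
    n_points: int


def precision_rms_3d(
    result: RegistrationResult,
    cameras: Sequence[CameraModel],
    cloud: PointCloud,
) -> PrecisionReport:
    """Registration precision from the stored final correspondence.

    Each matched edge point is back-projected into object space along its
    viewing ray at the depth of its matched (registered) model point; the
    RMS of the 3D distances to those model points measures how precisely
    the registered surface explains the detected edges.
    """
    if result.correspondences is None:
        raise InvalidArgumentError("result carries no stored correspondence")
    moved = result.apply(cloud).points
    diffs = []
    for cam, cc in zip(cameras, result.correspondences.per_camera):
        idx = cc.model_idx[cc.active]
        master = cc.master_xy[cc.active]
        for pt, mi in zip(master, idx):
            bp = backproject_at_depth(cam, pt, moved[mi])
            diffs.append(bp - moved[mi])
    if not diffs:
        raise InvalidArgumentError("no active correspondences")
    diffs = np.array(diffs)
    return PrecisionReport(
        rms_distance=float(np.sqrt(np.mean(np.sum(diffs**2, axis=1)))),
        rms_axis=np.sqrt(np.mean(diffs**2, axis=0)),
        n_points=len(diffs),
    )


def render_overlay(image: np.ndarray, camera: CameraModel, result: RegistrationResult, cloud: PointCloud, path) -> None:
    """Write a QA overlay PNG: radiograph with the projected outline of the
    registered model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outline = project_outline(camera, result.pose, result.lam if result.lam else 1.0, cloud)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(image), cmap="gray", origin="upper")
    ax.plot(outline.points[:, 0], outline.points[:, 1], ".", ms=2, color="tab:red")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
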