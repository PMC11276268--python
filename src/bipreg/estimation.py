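"""The one-step projection estimator and the two-step RSA baseline.

The projection estimator recovers the rigid (or scale-augmented) pose of
a 3D model directly from 2D image measurements by minimizing, over both
cameras jointly,

    sum_i || (x_i^p, y_i^p) - (x_i^m, y_i^m) ||^2  ->  min,

where the projected ("slave") coordinates come from the collinearity
equations applied to the transformed model and the master coordinates
are the extracted image measurements.  The rotation is parameterized by
a unit quaternion, whose norm condition g(q) = q0^2+q1^2+q2^2+q3^2 = 1
enters the design matrix as an extra constraint row; the constraint is
handled as a heavily weighted pseudo-observation followed by
renormalization.  Mismatched pairs are rejected by a 3-sigma rule on the
residual distances.

The classical two-step baseline (RSA: triangulate each marker, then fit
a rigid transform with Horn's closed-form absolute orientation) is
provided for comparison; its first-step errors propagate into the
second step, which is exactly what the one-step method avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    DegenerateDataError,
    DegenerateGeometryError,
    ImplausibleScaleWarning,
    InsufficientObservationsError,
    InvalidArgumentError,
    RankDeficiencyError,
)
from .geometry import (
    CameraModel,
    PointCloud,
    Pose,
    QuatPose,
    apply_scaled,
    matrix_to_euler,
    matrix_to_quat,
    project,
    quat_rotation_derivatives,
    quat_to_matrix,
    triangulate,
)

__all__ = [
    "CameraCorrespondences",
    "CorrespondenceSet",
    "RegistrationOptions",
    "RegistrationResult",
    "AccuracyReport",
    "build_jacobian",
    "solve_constrained_step",
    "reject_outliers",
    "match_nearest_one_to_one",
    "register",
    "fit_constant_scale",
    "horn_absolute_orientation",
    "rsa_register",
    "accuracy_report",
]


# ---------------------------------------------------------------------------
# correspondences


@dataclass
class CameraCorrespondences:
    """Matched pairs for one camera: master image points vs model indices."""

    master_xy: np.ndarray  # (M, 2) px
    model_idx: np.ndarray  # (M,) indices into the model cloud
    active: np.ndarray = None  # (M,) bool; False marks rejected pairs
    master_rows: Optional[np.ndarray] = None  # provenance rows in the source master set

    def __post_init__(self):
        self.master_xy = np.atleast_2d(np.asarray(self.master_xy, dtype=float))
        self.model_idx = np.asarray(self.model_idx, dtype=int)
        if self.active is None:
            self.active = np.ones(len(self.model_idx), dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
        if len(self.master_xy) != len(self.model_idx) or len(self.active) != len(self.model_idx):
            raise InvalidArgumentError("correspondence arrays must have equal length")
        act = self.model_idx[self.active]
        if len(np.unique(act)) != len(act):
            raise InvalidArgumentError("a model index appears twice in one camera's active set")


@dataclass
class CorrespondenceSet:
    """Per-camera correspondences feeding one joint least-squares solve."""

    per_camera: list[CameraCorrespondences]

    @property
    def n_active(self) -> int:
        return int(sum(c.active.sum() for c in self.per_camera))

    @property
    def n_rejected(self) -> int:
        return int(sum((~c.active).sum() for c in self.per_camera))


def match_nearest_one_to_one(master_xy: np.ndarray, slave_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass nearest-point matching used throughout the registration.

    Pass 1: every master point claims its nearest slave point.  Pass 2:
    a slave point claimed by several masters keeps only the claim with
    the shortest distance, so the result is one-to-one (injective in the
    slave points).

    Returns ``(master_rows, slave_cols)`` index arrays of the surviving
    pairs, ordered by master row.
    """
    from scipy.spatial import cKDTree

    master_xy = np.atleast_2d(np.asarray(master_xy, dtype=float))
    slave_xy = np.atleast_2d(np.asarray(slave_xy, dtype=float))
    if len(master_xy) == 0 or len(slave_xy) == 0:
        raise InvalidArgumentError("matching requires non-empty master and slave sets")
    dist, nearest = cKDTree(slave_xy).query(master_xy)
    keep = {}
    for mi, (si, d) in enumerate(zip(nearest, dist)):
        if si not in keep or d < keep[si][1]:
            keep[si] = (mi, d)
    pairs = sorted((mi, si) for si, (mi, _) in keep.items())
    rows = np.array([p[0] for p in pairs], dtype=int)
    cols = np.array([p[1] for p in pairs], dtype=int)
    return rows, cols


# ---------------------------------------------------------------------------
# design matrix


def _scaled_points(cloud: PointCloud, lam: Optional[float]) -> np.ndarray:
    if lam is None or lam == 1.0:
        return cloud.points
    c = cloud.centroid
    return c + lam * (cloud.points - c)


def build_jacobian(
    q_pose: QuatPose,
    lam: Optional[float],
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    corr: CorrespondenceSet,
):
    """Design matrix, residual vector and quaternion-constraint row.

    Parameters are ordered ``(Xt, Yt, Zt, q0, q1, q2, q3[, lam])``; the
    scale column is present only when ``lam`` is given.  Residuals are
    ``master - projected`` in px, two rows (x, y) per active pair.  The
    constraint row is the gradient of g = sum(q^2) with residual
    ``1 - g``.

    Distortion corrections are treated as locally constant in the
    derivatives (they vary on the scale of the whole image, the
    parameter step on the scale of a pixel).
    """
    q = np.asarray(q_pose.q, dtype=float)
    t = q_pose.translation
    estimate_scale = lam is not None
    n_par = 8 if estimate_scale else 7
    n_active = corr.n_active
    if n_active * 2 < n_par - 1:
        raise InsufficientObservationsError(
            f"{n_active} active pairs give {2 * n_active} equations for {n_par} unknowns"
        )

    r_mat = quat_to_matrix(q / np.linalg.norm(q))
    dr = quat_rotation_derivatives(q)
    centroid = cloud.centroid
    s_pts = _scaled_points(cloud, lam if estimate_scale else None)

    rows_a, rows_l = [], []
    for cam, cc in zip(cameras, corr.per_camera):
        if not np.any(cc.active):
            continue
        idx = cc.model_idx[cc.active]
        master = cc.master_xy[cc.active]
        s = s_pts[idx]  # (m, 3) scaled model points
        x_obj = s @ r_mat.T + t  # transformed points in object space
        m_cam = cam.rotation
        uvw = (x_obj - cam.position) @ m_cam.T
        u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise DegenerateGeometryError("model point in the principal plane during linearization")
        x_proj = cam.xp - cam.c * u / w
        y_proj = cam.yp - cam.c * v / w
        ddx, ddy = cam.distortion(x_proj, y_proj)
        x_proj, y_proj = x_proj + ddx, y_proj + ddy

        # chain rule: d(x, y)/d(U, V, W) times d(U, V, W)/d(params)
        m = len(idx)
        duvw = np.zeros((m, 3, n_par))
        duvw[:, :, 0:3] = np.broadcast_to(m_cam, (m, 3, 3))  # translation
        for k in range(4):
            duvw[:, :, 3 + k] = (s @ dr[k].T) @ m_cam.T
        if estimate_scale:
            duvw[:, :, 7] = ((cloud.points[idx] - centroid) @ r_mat.T) @ m_cam.T

        cw = cam.c / w
        dx_dp = -cw[:, None] * (duvw[:, 0, :] - (u / w)[:, None] * duvw[:, 2, :])
        dy_dp = -cw[:, None] * (duvw[:, 1, :] - (v / w)[:, None] * duvw[:, 2, :])

        a_cam = np.empty((2 * m, n_par))
        a_cam[0::2] = dx_dp
        a_cam[1::2] = dy_dp
        l_cam = np.empty(2 * m)
        l_cam[0::2] = master[:, 0] - x_proj
        l_cam[1::2] = master[:, 1] - y_proj
        rows_a.append(a_cam)
        rows_l.append(l_cam)

    a = np.vstack(rows_a)
    l = np.concatenate(rows_l)
    g_row = np.zeros(n_par)
    g_row[3:7] = 2.0 * q
    g_resid = 1.0 - float(q @ q)
    return a, l, g_row, g_resid


def solve_constrained_step(
    design: np.ndarray,
    residuals: np.ndarray,
    constraint_row: np.ndarray,
    constraint_resid: float,
    constraint_weight: float = 1e6,
    damping: float = 0.0,
) -> np.ndarray:
    """One Gauss-Newton step of the constrained problem.

    The unit-norm condition enters as a pseudo-observation with weight
    ``constraint_weight`` relative to unit-weight pixel observations.
    ``damping`` adds a Levenberg-Marquardt term ``mu * diag(N)`` for
    steps where the undamped update would increase the objective.
    """
    n = design.T @ design + constraint_weight * np.outer(constraint_row, constraint_row)
    b = design.T @ residuals + constraint_weight * constraint_row * constraint_resid
    if damping > 0.0:
        d = np.diag(n).copy()
        d[d <= 0] = 1.0
        n = n + damping * np.diag(d)
    cond = np.linalg.cond(n)
    if not np.isfinite(cond) or cond > 1e14:
        w_eig, v_eig = np.linalg.eigh(n)
        raise RankDeficiencyError(
            f"normal matrix singular (condition number {cond:.3g})",
            null_direction=v_eig[:, 0],
        )
    return np.linalg.solve(n, b)


# ---------------------------------------------------------------------------
# outlier rejection


def _residual_distances(residuals: np.ndarray) -> np.ndarray:
    r = residuals.reshape(-1, 2)
    return np.hypot(r[:, 0], r[:, 1])


def reject_outliers(corr: CorrespondenceSet, residuals: np.ndarray, k: float = 3.0) -> CorrespondenceSet:
    """Flag matching pairs whose residual distance is an outlier.

    A pair is rejected when its distance exceeds the mean of the active
    distances by more than ``k`` standard deviations (all-equal
    distances therefore reject nothing).  Applied batchwise, once per
    outer iteration; the rule is idempotent once no pair exceeds the
    threshold.  ``residuals`` is the stacked (x, y) residual vector over
    active pairs, in the camera order of ``corr``.
    """
    n_active = corr.n_active
    if n_active < 2:
        raise DegenerateDataError("outlier rejection needs at least 2 active pairs")
    d = _residual_distances(residuals)
    if len(d) != n_active:
        raise InvalidArgumentError("residual vector does not match the active pair count")
    bad = (d - d.mean()) > k * d.std()
    if np.all(bad):
        raise DegenerateDataError("all matching pairs rejected as outliers")
    out = []
    pos = 0
    for cc in corr.per_camera:
        active = cc.active.copy()
        m = int(active.sum())
        sel = np.nonzero(active)[0]
        active[sel[bad[pos : pos + m]]] = False
        pos += m
        out.append(CameraCorrespondences(cc.master_xy, cc.model_idx, active, cc.master_rows))
    return CorrespondenceSet(out)


# ---------------------------------------------------------------------------
# results


@dataclass
class RegistrationOptions:
    """Tunables of the iterative solve; defaults suit bead registration."""

    mode: str = "rigid"  # "rigid" | "scaled"
    max_iter: int = 100  # inner Gauss-Newton iterations per correspondence
    max_outer: int = 50  # correspondence / rejection rounds
    tol: float = 1e-8  # max |parameter update| (mm / quaternion units)
    outer_tol: float = 1e-5  # parameter stability across re-matching rounds
    outlier_k: float = 3.0
    reject_rounds: int = 5  # re-matching rounds during which 3-sigma rejection may add exclusions
    assignment: str = "nearest"  # "nearest" (two-pass rule) | "optimal" (assignment problem)
    constraint_weight: float = 1e6
    fixed_lam: Optional[float] = None  # register at a frozen scale factor
    reject: bool = True


@dataclass
class RegistrationResult:
    """Estimated pose with fit statistics.

    ``param_sigmas`` holds the a-posteriori standard deviations of
    (X, Y, Z) in mm and (omega, phi, kappa) in degrees, propagated from
    the inverse normal matrix scaled by the variance factor
    ``sigma0^2 = r'r / (2 n_active - n_params)``.
    """

    pose: Pose
    lam: Optional[float]
    rms_2d: float
    param_sigmas: Optional[dict] = None
    lam_sigma: Optional[float] = None
    iterations: int = 0
    n_rejected: int = 0
    converged: bool = False
    correspondences: Optional[CorrespondenceSet] = None
    objective: float = np.inf
    message: str = ""

    def apply(self, cloud: PointCloud) -> PointCloud:
        """Transform a cloud by the estimated pose (and scale, if any)."""
        return apply_scaled(self.pose, self.lam if self.lam is not None else 1.0, cloud)


def _objective(a_l: np.ndarray) -> float:
    return float(a_l @ a_l)


def _project_residuals(q_pose, lam, cloud, cameras, corr):
    """Stacked master-minus-projected residuals over active pairs."""
    s_pts = _scaled_points(cloud, lam)
    moved = s_pts @ q_pose.matrix.T + q_pose.translation
    out = []
    for cam, cc in zip(cameras, corr.per_camera):
        if not np.any(cc.active):
            continue
        proj = project(cam, moved[cc.model_idx[cc.active]])
        out.append((cc.master_xy[cc.active] - proj).ravel())
    return np.concatenate(out)


def _solve_pose(q_pose, lam, cloud, cameras, corr, opts) -> tuple[QuatPose, Optional[float], np.ndarray, int, bool]:
    """Inner loop: Gauss-Newton with LM fallback at fixed correspondences.

    ``lam`` is None in rigid mode; in scaled mode the scale column is part
    of the design matrix and updated with the pose.
    """
    estimate_scale = opts.mode == "scaled"
    cur_lam = lam if estimate_scale else None
    for it in range(1, opts.max_iter + 1):
        a, l, g_row, g_res = build_jacobian(q_pose, cur_lam, cloud, cameras, corr)
        f0 = _objective(l)
        damping = 0.0
        for _ in range(25):
            try:
                delta = solve_constrained_step(a, l, g_row, g_res, opts.constraint_weight, damping)
            except RankDeficiencyError:
                if damping == 0.0:
                    damping = 1e-6
                    continue
                raise
            q_new = q_pose.q + delta[3:7]
            q_new = q_new / np.linalg.norm(q_new)
            cand = QuatPose(q_pose.Xt + delta[0], q_pose.Yt + delta[1], q_pose.Zt + delta[2], q_new)
            cand_lam = cur_lam + delta[7] if estimate_scale else None
            f1 = _objective(_project_residuals(cand, cand_lam, cloud, cameras, corr))
            if f1 <= f0 + 1e-12 * (1.0 + f0):
                break
            damping = 1e-4 if damping == 0.0 else damping * 10.0
        else:
            return q_pose, cur_lam, l, it, False  # no acceptable step found
        # effective update: renormalization removes the radial quaternion
        # component the weighted constraint could not fully suppress
        step = max(
            float(np.max(np.abs(delta[:3]))),
            float(np.max(np.abs(cand.q - q_pose.q))),
            abs(delta[7]) if estimate_scale else 0.0,
        )
        q_pose, cur_lam = cand, cand_lam
        stalled = (f0 - f1) <= 1e-10 * (1.0 + f0) and it > 1
        if step < opts.tol or stalled:
            a, l, g_row, g_res = build_jacobian(q_pose, cur_lam, cloud, cameras, corr)
            return q_pose, cur_lam, l, it, True
    a, l, g_row, g_res = build_jacobian(q_pose, cur_lam, cloud, cameras, corr)
    return q_pose, cur_lam, l, opts.max_iter, False


def _euler_sigmas_from_quat_cov(q: np.ndarray, cov_q: np.ndarray) -> np.ndarray:
    """Propagate a 4x4 quaternion covariance to Euler-angle sigmas (deg)."""
    j = np.zeros((3, 4))
    h = 1e-7
    base = np.array(matrix_to_euler(quat_to_matrix(q / np.linalg.norm(q))))
    for k in range(4):
        e = np.zeros(4)
        e[k] = h
        qp = (q + e) / np.linalg.norm(q + e)
        qm = (q - e) / np.linalg.norm(q - e)
        ap = np.array(matrix_to_euler(quat_to_matrix(qp)))
        am = np.array(matrix_to_euler(quat_to_matrix(qm)))
        d = ap - am
        d = (d + np.pi) % (2 * np.pi) - np.pi  # guard angle wrap
        j[:, k] = d / (2 * h)
    cov_e = j @ cov_q @ j.T
    return np.rad2deg(np.sqrt(np.clip(np.diag(cov_e), 0.0, None)))


def _covariance_report(q_pose, lam, cloud, cameras, corr, opts):
    estimate_scale = opts.mode == "scaled"
    a, l, g_row, _ = build_jacobian(q_pose, lam if estimate_scale else None, cloud, cameras, corr)
    n_par = a.shape[1]
    redundancy = len(l) - (n_par - 1)  # the constraint removes one dof
    n = a.T @ a + opts.constraint_weight * np.outer(g_row, g_row)
    try:
        n_inv = np.linalg.inv(n)
    except np.linalg.LinAlgError:
        return None, None, float(np.sqrt(np.mean(l**2)))
    rms = float(np.sqrt(np.mean(l**2)))
    sigma0_sq = float(l @ l) / max(redundancy, 1)
    cov = sigma0_sq * n_inv
    sig_t = np.sqrt(np.clip(np.diag(cov)[:3], 0.0, None))
    sig_e = _euler_sigmas_from_quat_cov(q_pose.q, cov[3:7, 3:7])
    sigmas = {
        "X": float(sig_t[0]),
        "Y": float(sig_t[1]),
        "Z": float(sig_t[2]),
        "omega": float(sig_e[0]),
        "phi": float(sig_e[1]),
        "kappa": float(sig_e[2]),
    }
    lam_sigma = float(np.sqrt(max(cov[7, 7], 0.0))) if (estimate_scale and n_par == 8) else None
    return sigmas, lam_sigma, rms


def register(
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    master_points: Sequence[np.ndarray],
    init: Pose | QuatPose,
    opts: Optional[RegistrationOptions] = None,
) -> RegistrationResult:
    """One-step projection registration of a model cloud to image points.

    Outer loop per iteration: (a) project the model at the current
    parameters, (b) establish nearest-point one-to-one correspondence
    between the extracted master points and the projections, (c) solve
    the quaternion-constrained least squares to convergence, (d) reject
    3-sigma mismatches and re-solve.  Stops when the correspondence is
    stable and the parameter update fell below tolerance.

    ``master_points`` is one (M_c, 2) array of extracted image points per
    camera.  In scaled mode the scale factor is estimated jointly unless
    ``opts.fixed_lam`` freezes it.
    """
    opts = opts or RegistrationOptions()
    if opts.mode not in ("rigid", "scaled"):
        raise InvalidArgumentError(f"unknown mode {opts.mode!r}")
    if len(cloud) < 3:
        raise InvalidArgumentError("registration needs at least 3 model points")
    if len(cameras) != len(master_points):
        raise InvalidArgumentError("one master point set per camera required")

    q_pose = init.to_quat_pose() if isinstance(init, Pose) else init.normalized()
    # a frozen scale is folded into the model once; the solve is then rigid
    fixed_scale = opts.mode == "scaled" and opts.fixed_lam is not None
    if fixed_scale:
        from .geometry import scale_about_centroid

        work_cloud = scale_about_centroid(opts.fixed_lam, cloud)
        work_opts = replace(opts, mode="rigid", fixed_lam=None)
    else:
        work_cloud, work_opts = cloud, opts
    lam = 1.0 if work_opts.mode == "scaled" else None

    prev_pairs = None
    total_iters = 0
    last_l = None
    corr = None
    converged = False
    message = ""
    for outer in range(1, opts.max_outer + 1):
        moved = _scaled_points(work_cloud, lam) @ q_pose.matrix.T + q_pose.translation
        per_cam = []
        for cam, master in zip(cameras, master_points):
            proj = project(cam, moved)
            master = np.atleast_2d(master)
            if opts.assignment == "optimal" and master.shape[0] * proj.shape[0] <= 40000:
                # globally optimal assignment: far more robust than greedy
                # nearest-point matching when the start is a large rotation
                # away (used by the coarse pose search)
                from scipy.optimize import linear_sum_assignment

                cost = np.linalg.norm(master[:, None] - proj[None], axis=-1)
                rows, cols = linear_sum_assignment(cost)
            else:
                rows, cols = match_nearest_one_to_one(master, proj)
            per_cam.append(CameraCorrespondences(master[rows], cols))
        corr = CorrespondenceSet(per_cam)

        q_pose, lam, l, iters, ok = _solve_pose(q_pose, lam, work_cloud, cameras, corr, work_opts)
        total_iters += iters
        if opts.reject and corr.n_active > 2:
            try:
                corr2 = reject_outliers(corr, l, opts.outlier_k)
            except DegenerateDataError:
                corr2 = corr
            if corr2.n_rejected > corr.n_rejected:
                corr = corr2
                q_pose, lam, l, iters, ok = _solve_pose(q_pose, lam, work_cloud, cameras, corr, work_opts)
                total_iters += iters
        last_l = l

        pairs = tuple(
            (ci, int(i), int(j))
            for ci, cc in enumerate(corr.per_camera)
            for i, j in zip(np.nonzero(cc.active)[0], cc.model_idx[cc.active])
        )
        if ok and pairs == prev_pairs:
            converged = True
            break
        prev_pairs = pairs
    else:
        message = f"no stable correspondence after {opts.max_outer} outer iterations"

    out_lam = opts.fixed_lam if fixed_scale else lam
    if out_lam is not None and not (0.5 <= out_lam <= 2.0):
        warnings.warn(
            f"estimated scale factor {out_lam:.4f} outside the plausible range [0.5, 2]",
            ImplausibleScaleWarning,
        )
    sigmas, lam_sigma, rms = _covariance_report(q_pose, lam, work_cloud, cameras, corr, work_opts)
    return RegistrationResult(
        pose=q_pose.to_pose(),
        lam=out_lam,
        rms_2d=rms,
        param_sigmas=sigmas,
        lam_sigma=lam_sigma,
        iterations=total_iters,
        n_rejected=corr.n_rejected,
        converged=converged,
        correspondences=corr,
        objective=_objective(last_l),
        message=message,
    )


def fit_constant_scale(
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    master_per_epoch: Sequence[Sequence[np.ndarray]],
    inits: Sequence[Pose],
    opts: Optional[RegistrationOptions] = None,
) -> tuple[float, list[RegistrationResult]]:
    """Trial-constant scale factor: average the per-epoch estimates, then
    re-register every epoch with the scale frozen at that mean.

    Returns ``(lam_bar, fixed-scale results)``.
    """
    opts = opts or RegistrationOptions(mode="scaled")
    lams = []
    for master, init in zip(master_per_epoch, inits):
        res = register(cloud, cameras, master, init, replace(opts, mode="scaled", fixed_lam=None))
        lams.append(res.lam)
    lam_bar = float(np.mean(lams))
    fixed = [
        register(cloud, cameras, master, init, replace(opts, mode="scaled", fixed_lam=lam_bar))
        for master, init in zip(master_per_epoch, inits)
    ]
    return lam_bar, fixed


# ---------------------------------------------------------------------------
# RSA baseline


def horn_absolute_orientation(p: np.ndarray, q: np.ndarray) -> Pose:
    """Closed-form least-squares rigid transform P -> Q (Horn's method).

    Builds the 4x4 quaternion profile matrix from the centered
    cross-covariance and takes its dominant eigenvector; translation
    follows from the centroids.  Requires >= 3 non-collinear pairs.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.shape != q.shape or p.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 matched point pairs of equal shape")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    a = p - pc
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise DegenerateGeometryError("collinear point configuration; rotation not unique")
    s = a.T @ (q - qc)
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w_eig, v_eig = np.linalg.eigh(n)
    quat = v_eig[:, -1]
    if quat[0] < 0:
        quat = -quat
    r = quat_to_matrix(quat)
    t = qc - r @ pc
    return Pose.from_matrix(r, t)


def rsa_register(
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    master_points: Sequence[np.ndarray],
    correspondence: Sequence[np.ndarray],
) -> RegistrationResult:
    """Two-step RSA baseline: triangulate each marker, then Horn's fit.

    ``correspondence[c][k]`` gives the model (bead) index of master row
    ``k`` in camera ``c``.  Beads seen in only one camera are excluded
    with a warning; fewer than 3 usable beads is an error.  ``rms_2d``
    is computed by reprojecting the fitted pose.
    """
    if len(cameras) != 2:
        raise InvalidArgumentError("the RSA baseline expects exactly two cameras")
    maps = []
    for master, idx in zip(master_points, correspondence):
        master = np.atleast_2d(np.asarray(master, dtype=float))
        maps.append({int(i): master[k] for k, i in enumerate(np.asarray(idx, dtype=int))})
    common = sorted(set(maps[0]) & set(maps[1]))
    missing = sorted((set(maps[0]) | set(maps[1])) - set(common))
    if missing:
        warnings.warn(f"beads {missing} observed in only one camera; excluded from RSA")
    if len(common) < 3:
        raise InsufficientObservationsError(f"only {len(common)} beads seen in both cameras; need >= 3")
    tri = np.array([triangulate(cameras[0], cameras[1], maps[0][i], maps[1][i]) for i in common])
    pose = horn_absolute_orientation(cloud.points[common], tri)
    moved = cloud.points @ pose.matrix.T + pose.translation
    res = []
    per_cam = []
    for cam, m in zip(cameras, maps):
        idx = np.array(common)
        proj = project(cam, moved[idx])
        master = np.array([m[i] for i in common])
        res.append((master - proj).ravel())
        per_cam.append(CameraCorrespondences(master, idx))
    r = np.concatenate(res)
    return RegistrationResult(
        pose=pose,
        lam=None,
        rms_2d=float(np.sqrt(np.mean(r**2))),
        iterations=1,
        converged=True,
        correspondences=CorrespondenceSet(per_cam),
        objective=float(r @ r),
    )


# ---------------------------------------------------------------------------
# accuracy reporting


@dataclass
class AccuracyReport:
    """Parameter differences and 3D marker-distance RMS vs a reference.

    ``d_params``: estimated minus reference for (X, Y, Z) in mm and
    (omega, phi, kappa) in degrees.  ``rms_axis``: per-axis RMS of the
    bead coordinate differences; ``rms_distance``: RMS of the Euclidean
    bead distances.
    """

    d_params: dict
    rms_axis: np.ndarray
    rms_distance: float


def accuracy_report(result: RegistrationResult, truth: RegistrationResult, bead_cloud: PointCloud) -> AccuracyReport:
    """Compare a registration against a reference on the same bead cloud.

    Bead coordinates are computed with the rigid part of each result
    only: the scale factor models a systematic 2D edge-detection offset,
    not a physical size change of the (rigid) bone, so the physical
    marker positions follow the pose alone.
    """
    dp = {
        "X": result.pose.Xt - truth.pose.Xt,
        "Y": result.pose.Yt - truth.pose.Yt,
        "Z": result.pose.Zt - truth.pose.Zt,
    }
    for key in ("omega", "phi", "kappa"):
        d = getattr(result.pose, key) - getattr(truth.pose, key)
        dp[key] = float(np.rad2deg((d + np.pi) % (2 * np.pi) - np.pi))
    from .geometry import apply_rigid

    b_res = apply_rigid(result.pose, bead_cloud).points
    b_tru = apply_rigid(truth.pose, bead_cloud).points
    diff = b_res - b_tru
    rms_axis = np.sqrt(np.mean(diff**2, axis=0))
    rms_dist = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return AccuracyReport(d_params=dp, rms_axis=rms_axis, rms_distance=rms_dist)
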