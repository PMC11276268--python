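"""The projection estimator, its design matrix, outlier handling, the
scale mode, Horn's closed form and the RSA baseline."""

import numpy as np
import pytest

from bipreg.exceptions import (
    DegenerateDataError,
    DegenerateGeometryError,
    InsufficientObservationsError,
)
from bipreg.estimation import (
    CameraCorrespondences,
    CorrespondenceSet,
    RegistrationOptions,
    accuracy_report,
    build_jacobian,
    horn_absolute_orientation,
    match_nearest_one_to_one,
    register,
    reject_outliers,
    rsa_register,
    solve_constrained_step,
)
from bipreg.geometry import (
    PointCloud,
    Pose,
    QuatPose,
    apply_rigid,
    project,
    scale_about_centroid,
)


def full_correspondence(beads, master):
    return CorrespondenceSet(
        [CameraCorrespondences(m, np.arange(len(beads))) for m in master]
    )


def raw_quat_rotation(q):
    """Oracle: homogeneous 9-term quaternion expansion, no normalization."""
    q0, q1, q2, q3 = q
    return np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    )


def forward_projections(params, beads, cameras, corr, with_scale):
    """Oracle forward model for finite differences: raw quaternion
    expansion, scaling about the centroid, collinearity projection."""
    t, q = params[:3], params[3:7]
    lam = params[7] if with_scale else 1.0
    c0 = beads.centroid
    s = c0 + lam * (beads.points - c0)
    moved = s @ raw_quat_rotation(q).T + t
    out = []
    for cam, cc in zip(cameras, corr.per_camera):
        uvw = (moved[cc.model_idx] - cam.position) @ cam.rotation.T
        x = cam.xp - cam.c * uvw[:, 0] / uvw[:, 2]
        y = cam.yp - cam.c * uvw[:, 1] / uvw[:, 2]
        out.append(np.stack([x, y], 1).ravel())
    return np.concatenate(out)


class TestJacobian:
    def test_matches_central_finite_differences(self, beads, rig, true_pose, master_exact):
        corr = full_correspondence(beads, master_exact)
        qp = true_pose.to_quat_pose()
        a, l, g_row, g_res = build_jacobian(qp, 0.97, beads, rig, corr)
        p0 = np.concatenate([qp.translation, qp.q, [0.97]])
        h = 1e-6
        fd = np.zeros_like(a)
        for k in range(8):
            e = np.zeros(8)
            e[k] = h
            fd[:, k] = (
                forward_projections(p0 + e, beads, rig, corr, True)
                - forward_projections(p0 - e, beads, rig, corr, True)
            ) / (2 * h)
        assert np.abs(a - fd).max() < 1e-5

    def test_constraint_row_at_unit_real_quaternion(self, beads, rig, master_exact):
        corr = full_correspondence(beads, master_exact)
        qp = QuatPose(0, 0, 0, np.array([1.0, 0, 0, 0]))
        _, _, g_row, g_res = build_jacobian(qp, None, beads, rig, corr)
        assert np.allclose(g_row, [0, 0, 0, 2, 0, 0, 0])
        assert g_res == 0.0

    def test_translation_columns_match_finite_differences(self, beads, rig, true_pose, master_exact):
        corr = full_correspondence(beads, master_exact)
        qp = true_pose.to_quat_pose()
        a, *_ = build_jacobian(qp, None, beads, rig, corr)
        p0 = np.concatenate([qp.translation, qp.q])
        h = 1e-6
        for k in range(3):
            e = np.zeros(7)
            e[k] = h
            fd = (
                forward_projections(p0 + e, beads, rig, corr, False)
                - forward_projections(p0 - e, beads, rig, corr, False)
            ) / (2 * h)
            assert np.abs(a[:, k] - fd).max() < 1e-5

    def test_underdetermined_raises_with_counts(self, beads, rig, master_exact):
        corr = CorrespondenceSet([CameraCorrespondences(master_exact[0][:1], [0])])
        with pytest.raises(InsufficientObservationsError, match="1 active"):
            build_jacobian(QuatPose(0, 0, 0, np.array([1.0, 0, 0, 0])), None, beads, [rig[0]], corr)


class TestConstrainedStep:
    def test_zero_residuals_give_zero_update(self, beads, rig, true_pose, master_exact):
        corr = full_correspondence(beads, master_exact)
        a, l, g_row, g_res = build_jacobian(true_pose.to_quat_pose(), None, beads, rig, corr)
        delta = solve_constrained_step(a, l, g_row, g_res)
        assert np.abs(delta).max() < 1e-9

    def test_pure_translation_misfit_recovered_quadratically(self, beads, rig, true_pose, master_exact):
        # the projection is a ratio of affine functions of the translation,
        # so one Gauss-Newton step leaves a small rational remainder; the
        # iteration is quadratic and reaches 1e-6 mm within three steps
        shifted = Pose(true_pose.Xt + 1, true_pose.Yt + 2, true_pose.Zt + 3, true_pose.omega, true_pose.phi, true_pose.kappa)
        corr = full_correspondence(beads, master_exact)
        qp = shifted.to_quat_pose()
        errs = []
        for _ in range(3):
            a, l, g_row, g_res = build_jacobian(qp, None, beads, rig, corr)
            d = solve_constrained_step(a, l, g_row, g_res)
            q_new = qp.q + d[3:7]
            qp = QuatPose(qp.Xt + d[0], qp.Yt + d[1], qp.Zt + d[2], q_new / np.linalg.norm(q_new))
            errs.append(np.abs(qp.translation - true_pose.translation).max())
        assert errs[0] < 0.05  # one step removes 99% of a 3 mm offset
        assert errs[-1] < 1e-6

    def test_iterated_steps_reach_grid_search_optimum(self, beads, rig, true_pose, master_exact, rng):
        opts = RegistrationOptions()
        init = Pose(
            true_pose.Xt + rng.normal(0, 0.5),
            true_pose.Yt + rng.normal(0, 0.5),
            true_pose.Zt + rng.normal(0, 0.5),
            true_pose.omega + rng.normal(0, 0.01),
            true_pose.phi + rng.normal(0, 0.01),
            true_pose.kappa + rng.normal(0, 0.01),
        )
        res = register(beads, rig, master_exact, init, opts)
        # oracle: dense grid search over a small neighborhood of the truth
        best = np.inf
        for dx in np.linspace(-0.02, 0.02, 5):
            for dk in np.linspace(-0.0005, 0.0005, 5):
                cand = Pose(true_pose.Xt + dx, true_pose.Yt, true_pose.Zt, true_pose.omega, true_pose.phi, true_pose.kappa + dk)
                r = np.concatenate(
                    [(m - project(cam, apply_rigid(cand, beads))).ravel() for cam, m in zip(rig, master_exact)]
                )
                best = min(best, r @ r)
        assert res.objective <= best + 1e-12


class TestOutlierRejection:
    def test_equal_residuals_reject_nothing(self, beads, master_exact):
        corr = full_correspondence(beads, master_exact)
        res = np.tile([3.0, 4.0], corr.n_active)  # all distances exactly 5
        out = reject_outliers(corr, res)
        assert out.n_rejected == 0

    def test_single_gross_outlier_rejected(self):
        # 20 distances of ~1 px and one of 50 px: sigma of the set computed
        # by hand puts only the large one beyond mean + 3 sigma
        n = 21
        corr = CorrespondenceSet([CameraCorrespondences(np.zeros((n, 2)), np.arange(n))])
        res = np.zeros(2 * n)
        res[0::2] = 1.0
        res[-2] = 50.0
        d = np.hypot(res[0::2], res[1::2])
        assert (d - d.mean() > 3 * d.std()).sum() == 1  # hand check of the construction
        out = reject_outliers(corr, res)
        assert out.n_rejected == 1
        assert not out.per_camera[0].active[-1]

    def test_idempotent_once_clean(self, beads, master_exact, rng):
        corr = full_correspondence(beads, master_exact)
        res = rng.normal(0, 0.3, 2 * corr.n_active)
        once = reject_outliers(corr, res)
        keep = np.concatenate([c.active for c in once.per_camera])
        res2 = res.reshape(-1, 2)[keep].ravel()
        twice = reject_outliers(once, res2)
        assert twice.n_rejected == once.n_rejected

    def test_all_rejected_raises(self):
        corr = CorrespondenceSet([CameraCorrespondences(np.zeros((2, 2)), [0, 1])])
        with pytest.raises(DegenerateDataError):
            # contrived: force rejection of everything via a negative k
            reject_outliers(corr, np.array([1.0, 0, 2.0, 0]), k=-2.0)


class TestRegister:
    def test_self_consistent_start_converges_immediately(self, beads, rig, true_pose, master_exact):
        res = register(beads, rig, master_exact, true_pose)
        assert res.converged and res.iterations <= 2
        assert res.rms_2d < 1e-9
        assert np.abs(res.pose.translation - true_pose.translation).max() < 1e-9
        assert np.abs(res.pose.angles_deg - true_pose.angles_deg).max() < 1e-9

    def test_perturbed_start_recovers_exactly(self, beads, rig, true_pose, master_exact):
        init = Pose.from_degrees(
            true_pose.Xt + 5, true_pose.Yt - 5, true_pose.Zt + 5,
            true_pose.angles_deg[0] + 5, true_pose.angles_deg[1] - 5, true_pose.angles_deg[2] + 5,
        )
        res = register(beads, rig, master_exact, init)
        assert res.converged
        assert np.abs(res.pose.translation - true_pose.translation).max() < 1e-6
        assert np.abs(res.pose.angles_deg - true_pose.angles_deg).max() < 1e-6

    def test_noisy_monte_carlo_rms_and_unbiasedness(self, beads, rig, true_pose, master_exact):
        init = Pose.from_degrees(
            true_pose.Xt + 5, true_pose.Yt - 5, true_pose.Zt + 5,
            true_pose.angles_deg[0] + 5, true_pose.angles_deg[1] - 5, true_pose.angles_deg[2] + 5,
        )
        rmss, errs = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            noisy = [m + r.normal(0, 0.5, m.shape) for m in master_exact]
            res = register(beads, rig, noisy, init)
            rmss.append(res.rms_2d)
            errs.append(np.r_[res.pose.translation - true_pose.translation,
                              res.pose.angles_deg - true_pose.angles_deg])
        assert 0.3 < np.mean(rmss) < 0.7
        errs = np.array(errs)
        sem = errs.std(axis=0) / np.sqrt(len(errs))
        assert np.all(np.abs(errs.mean(axis=0)) < 3 * sem + 1e-12)

    def test_objective_non_increasing_reported(self, beads, rig, true_pose, master_exact, rng):
        noisy = [m + rng.normal(0, 0.5, m.shape) for m in master_exact]
        res = register(beads, rig, noisy, true_pose)
        assert res.converged and np.isfinite(res.objective)


class TestScaleMode:
    def test_recovers_known_shrink_exactly(self, beads, rig, true_pose):
        shrunk = scale_about_centroid(0.9923, beads)
        master = [project(cam, apply_rigid(true_pose, shrunk)) for cam in rig]
        res = register(beads, rig, master, true_pose, RegistrationOptions(mode="scaled"))
        assert abs(res.lam - 0.9923) < 1e-6

    def test_unshrunk_model_gives_unit_scale(self, beads, rig, true_pose, master_exact):
        res = register(beads, rig, master_exact, true_pose, RegistrationOptions(mode="scaled"))
        assert abs(res.lam - 1.0) < 1e-9

    def test_noisy_scale_estimate_unbiased(self, beads, rig, true_pose):
        shrunk = scale_about_centroid(0.99, beads)
        master = [project(cam, apply_rigid(true_pose, shrunk)) for cam in rig]
        lams = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            noisy = [m + r.normal(0, 0.25, m.shape) for m in master]
            res = register(beads, rig, noisy, true_pose, RegistrationOptions(mode="scaled"))
            lams.append(res.lam)
        assert abs(np.mean(lams) - 0.99) < 1e-3

    def test_fixed_scale_registration_matches_joint_estimate(self, beads, rig, true_pose):
        shrunk = scale_about_centroid(0.9923, beads)
        master = [project(cam, apply_rigid(true_pose, shrunk)) for cam in rig]
        res = register(beads, rig, master, true_pose, RegistrationOptions(mode="scaled", fixed_lam=0.9923))
        assert res.lam == 0.9923
        assert res.rms_2d < 1e-9


class TestHorn:
    def test_exact_recovery(self, rng):
        p = rng.normal(size=(10, 3)) * 20
        pose = Pose.from_degrees(1, -2, 3, 20, -35, 60)
        q = apply_rigid(pose, PointCloud(p)).points
        est = horn_absolute_orientation(p, q)
        assert np.abs(est.matrix - pose.matrix).max() < 1e-10
        assert np.abs(est.translation - pose.translation).max() < 1e-10

    def test_beats_random_candidate_poses(self, rng):
        p = rng.normal(size=(12, 3)) * 20
        pose = Pose.from_degrees(1, -2, 3, 20, -35, 60)
        q = apply_rigid(pose, PointCloud(p)).points + rng.normal(0, 0.3, (12, 3))
        est = horn_absolute_orientation(p, q)
        obj = np.sum((q - (p @ est.matrix.T + est.translation)) ** 2)
        for _ in range(1000):
            cand = Pose.from_degrees(*rng.uniform(-5, 5, 3) + [1, -2, 3], *rng.uniform(-10, 10, 3) + [20, -35, 60])
            cobj = np.sum((q - (p @ cand.matrix.T + cand.translation)) ** 2)
            assert obj <= cobj + 1e-9

    def test_minimal_case_matches_svd_procrustes(self, rng):
        # oracle: SVD orthogonal Procrustes on the centered sets
        p = rng.normal(size=(3, 3)) * 10
        pose = Pose.from_degrees(0.5, 1.5, -2.5, 10, 25, -40)
        q = apply_rigid(pose, PointCloud(p)).points
        est = horn_absolute_orientation(p, q)
        pc, qc = p - p.mean(0), q - q.mean(0)
        u, _, vt = np.linalg.svd(qc.T @ pc)
        d = np.sign(np.linalg.det(u @ vt))
        r_svd = u @ np.diag([1, 1, d]) @ vt
        assert np.abs(est.matrix - r_svd).max() < 1e-9

    def test_collinear_points_raise(self):
        p = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            horn_absolute_orientation(p, p + 1.0)


class TestRSA:
    def test_noiseless_agrees_with_projection_method(self, beads, rig, true_pose, master_exact):
        corr = [np.arange(len(beads))] * 2
        res_rsa = rsa_register(beads, rig, master_exact, corr)
        res_proj = register(beads, rig, master_exact, true_pose)
        assert np.abs(res_rsa.pose.translation - res_proj.pose.translation).max() < 1e-9
        assert np.abs(res_rsa.pose.matrix - res_proj.pose.matrix).max() < 1e-9

    def test_projection_method_beats_rsa_under_noise(self, beads, rig, true_pose, master_exact):
        corr = [np.arange(len(beads))] * 2
        init = Pose.from_degrees(
            true_pose.Xt + 5, true_pose.Yt - 5, true_pose.Zt + 5,
            true_pose.angles_deg[0] + 5, true_pose.angles_deg[1] - 5, true_pose.angles_deg[2] + 5,
        )
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            noisy = [m + r.normal(0, 0.5, m.shape) for m in master_exact]
            res_p = register(beads, rig, noisy, init)
            res_r = rsa_register(beads, rig, noisy, corr)
            wins += res_p.rms_2d <= res_r.rms_2d
        assert wins >= 90

    def test_seven_beads_tighter_than_three(self, phantom, rig, true_pose):
        # marker redundancy: pose scatter with 7 beads < scatter with 3
        beads7 = phantom.bead_cloud()
        beads3 = PointCloud(beads7.points[:3])
        scatter = {}
        for cloud in (beads7, beads3):
            master = [project(cam, apply_rigid(true_pose, cloud)) for cam in rig]
            corr = [np.arange(len(cloud))] * 2
            est = []
            for seed in range(40):
                r = np.random.default_rng(seed)
                noisy = [m + r.normal(0, 0.5, m.shape) for m in master]
                res = rsa_register(cloud, rig, noisy, corr)
                est.append(np.r_[res.pose.translation, res.pose.angles_deg])
            scatter[len(cloud)] = np.array(est).std(axis=0)
        # redundancy tightens the pose overall; individual components can
        # trade off with the specific 3-bead geometry
        assert np.linalg.norm(scatter[7]) < np.linalg.norm(scatter[3])
        assert (scatter[7] < scatter[3]).sum() >= 5

    def test_missing_bead_excluded_with_warning(self, beads, rig, master_exact):
        corr = [np.arange(7), np.arange(6)]
        master = [master_exact[0], master_exact[1][:6]]
        with pytest.warns(UserWarning, match="excluded"):
            res = rsa_register(beads, rig, master, corr)
        assert res.converged

    def test_too_few_common_beads_raise(self, beads, rig, master_exact):
        with pytest.raises(InsufficientObservationsError):
            rsa_register(beads, rig, [master_exact[0][:2], master_exact[1][:2]], [np.arange(2), np.arange(2)])


class TestAccuracyReport:
    def test_identical_results_give_zeros(self, beads, true_pose):
        from bipreg.estimation import RegistrationResult

        res = RegistrationResult(pose=true_pose, lam=None, rms_2d=0.0)
        rep = accuracy_report(res, res, beads)
        assert all(v == 0 for v in rep.d_params.values())
        assert rep.rms_distance == 0.0

    def test_pure_depth_shift(self, beads, true_pose):
        from bipreg.estimation import RegistrationResult

        truth = RegistrationResult(pose=true_pose, lam=None, rms_2d=0.0)
        shifted = RegistrationResult(
            pose=Pose(true_pose.Xt, true_pose.Yt, true_pose.Zt + 0.5, true_pose.omega, true_pose.phi, true_pose.kappa),
            lam=None,
            rms_2d=0.0,
        )
        rep = accuracy_report(shifted, truth, beads)
        assert np.isclose(rep.d_params["Z"], 0.5)
        assert np.allclose(rep.rms_axis, [0, 0, 0.5], atol=1e-12)
        assert np.isclose(rep.rms_distance, 0.5)

    def test_random_perturbation_matches_direct_recomputation(self, beads, true_pose, rng):
        from bipreg.estimation import RegistrationResult

        other = Pose.from_degrees(*(true_pose.translation + rng.normal(0, 1, 3)),
                                  *(true_pose.angles_deg + rng.normal(0, 1, 3)))
        truth = RegistrationResult(pose=true_pose, lam=None, rms_2d=0.0)
        res = RegistrationResult(pose=other, lam=None, rms_2d=0.0)
        rep = accuracy_report(res, truth, beads)
        a = apply_rigid(other, beads).points
        b = apply_rigid(true_pose, beads).points
        assert np.isclose(rep.rms_distance, np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


class TestMatcher:
    def test_shortest_claim_wins(self):
        rows, cols = match_nearest_one_to_one(np.array([[0.0, 0], [1.0, 0]]), np.array([[0.1, 0]]))
        assert list(rows) == [0] and list(cols) == [0]

    def test_identical_sets_match_perfectly(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        rows, cols = match_nearest_one_to_one(pts, pts)
        assert np.array_equal(rows, cols)

    def test_matches_brute_force_two_pass_rule(self, rng):
        for _ in range(100):
            master = rng.uniform(0, 50, (50, 2))
            slave = rng.uniform(0, 50, (40, 2))
            rows, cols = match_nearest_one_to_one(master, slave)
            # oracle: brute force over all pairs
            d = np.linalg.norm(master[:, None] - slave[None], axis=-1)
            nearest = d.argmin(axis=1)
            best = {}
            for mi, si in enumerate(nearest):
                if si not in best or d[mi, si] < d[best[si], si]:
                    best[si] = mi
            expected = sorted((mi, si) for si, mi in best.items())
            assert [tuple(p) for p in zip(rows, cols)] == expected
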