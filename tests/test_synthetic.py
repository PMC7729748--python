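"""Kinematic-chain simulator: self-consistency of the emitted ground truth
and of the synthesized measurements."""

import numpy as np
import pytest

import kinegraph as kg
from kinegraph.factors import hinge_residual, joint_center_residual
from kinegraph.graph import HINGE_SPECS, JOINT_SPECS
from kinegraph.manifold import Pose
from kinegraph.synthetic import (
    MotionPrimitive,
    MotionScript,
    calibrate_covariances,
    forward_kinematics,
    make_skeleton,
    perturb_soft_tissue,
    script_motion_profile,
    synthesize_imu,
    truth_values,
)


class TestMakeSkeleton:
    def test_deterministic_given_seed(self):
        s1, s2 = make_skeleton(seed=7), make_skeleton(seed=7)
        assert s1.femur_length == s2.femur_length
        np.testing.assert_array_equal(s1.axes["r2"], s2.axes["r2"])
        np.testing.assert_array_equal(s1.offsets["s3ra"], s2.offsets["s3ra"])

    def test_lengths_within_hard_windows(self):
        for seed in range(25):
            sk = make_skeleton(seed=seed)
            assert 0.326 <= sk.femur_length <= 0.480
            assert 0.344 <= sk.tibia_length <= 0.479

    def test_axis_segment_angles_near_population_means(self):
        for seed in range(25):
            sk = make_skeleton(seed=seed)
            assert abs(sk.axis_angles_deg["right_femur"] - 84.0) <= 3 * 2.4
            assert abs(sk.axis_angles_deg["right_tibia"] - 92.0) <= 3 * 1.2
            assert abs(sk.axis_angles_deg["left_femur"] - 96.0) <= 3 * 2.4
            assert abs(sk.axis_angles_deg["left_tibia"] - 88.0) <= 3 * 1.2

    def test_axes_unit_norm_and_consistent_with_sampled_angles(self):
        sk = make_skeleton(seed=3)
        for name in ("r2", "r3", "r5", "r6"):
            assert np.linalg.norm(sk.axes[name]) == pytest.approx(1.0, abs=1e-12)
        # angle between IMU-frame axis and IMU-frame proximal vector matches
        d = sk.offsets["s2rh"] - sk.offsets["s2rk"]
        ang = np.degrees(np.arccos(sk.axes["r2"] @ d / np.linalg.norm(d)))
        assert ang == pytest.approx(sk.axis_angles_deg["right_femur"], abs=1e-9)

    def test_roundtrip_through_dict(self):
        sk = make_skeleton(seed=5)
        sk2 = kg.SkeletonTruth.from_dict(sk.to_dict())
        np.testing.assert_allclose(sk2.axes["r6"], sk.axes["r6"])
        np.testing.assert_allclose(sk2.mounts[2][0], sk.mounts[2][0])


class TestMotionScript:
    def test_contains_deep_knee_flexion(self):
        script = script_motion_profile(60.0, seed=0)
        knee_amp = [abs(p.amplitude) for p in script.primitives if "knee" in p.joint]
        assert knee_amp and min(knee_amp) >= 90.0

    def test_every_lower_body_dof_excited(self):
        script = script_motion_profile(40.0, seed=0)
        joints = {(p.joint, p.dof) for p in script.primitives}
        for side in ("right", "left"):
            assert (f"{side}_ankle", "flexion") in joints
            assert (f"{side}_ankle", "eversion") in joints
            assert (f"{side}_knee", "flexion") in joints
            for dof in ("flexion", "abduction", "rotation"):
                assert (f"{side}_hip", dof) in joints
        assert ("pelvis", "twist") in joints

    def test_deterministic(self):
        s1 = script_motion_profile(45.0, seed=9)
        s2 = script_motion_profile(45.0, seed=9)
        assert [(p.joint, p.dof, p.amplitude) for p in s1.primitives] == [
            (p.joint, p.dof, p.amplitude) for p in s2.primitives
        ]

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="30"):
            script_motion_profile(10.0, seed=0)

    def test_excessive_knee_amplitude_rejected(self):
        with pytest.raises(ValueError, match="150"):
            MotionScript(
                [MotionPrimitive("right_knee", "flexion", -170.0, 1, 0.0, 5.0)],
                30.0, 0,
            )


class TestForwardKinematics:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth(skeleton):
        script = script_motion_profile(30.0, seed=1)
        return forward_kinematics(skeleton, script, rate=100.0)

    def test_zero_amplitude_script_is_static(self, skeleton):
        truth = forward_kinematics(
            skeleton, MotionScript([], 3.0, 0), rate=100.0
        )
        assert np.all(truth.R == truth.R[:1])
        assert not truth.v.any() and not truth.omega.any() and not truth.a.any()

    def test_joint_center_coherence_exact(self, truth, skeleton):
        for _, A, sA, B, sB in JOINT_SPECS:
            for k in range(0, len(truth.t), 157):
                e = joint_center_residual(
                    Pose(truth.R[k, A], truth.p[k, A]), skeleton.offsets[sA],
                    Pose(truth.R[k, B], truth.p[k, B]), skeleton.offsets[sB],
                )
                assert np.linalg.norm(e) < 1e-12

    def test_relative_angvel_parallel_to_true_hinge_axis(self, truth, skeleton):
        for axis, A, B in HINGE_SPECS:
            r = skeleton.axes[axis]
            for k in range(0, len(truth.t), 157):
                e = hinge_residual(
                    r, truth.R[k, A], truth.R[k, B], truth.omega[k, A], truth.omega[k, B]
                )
                assert np.linalg.norm(e) < 1e-10

    def test_finite_differences_converge_to_stored_derivatives(self, truth, skeleton):
        """Central differences of the stored positions/velocities approach
        the stored velocities/accelerations under rate refinement.

        Positions have continuous second derivatives everywhere, so the
        velocity check converges at O(dt^2). The joint-angle primitives are
        C^2 with third-derivative kinks, so acceleration converges at
        O(dt^2) away from the kink samples (checked via a high percentile)
        and at least first order in the worst case.
        """
        script = script_motion_profile(30.0, seed=1)
        fine = forward_kinematics(skeleton, script, rate=400.0)

        def fd_err(tr, src, ref, q=100.0):
            dt = tr.t[1] - tr.t[0]
            num = (src[2:] - src[:-2]) / (2 * dt)
            return np.percentile(np.abs(num - ref[1:-1]), q)

        ev_c = fd_err(truth, truth.p, truth.v)
        ev_f = fd_err(fine, fine.p, fine.v)
        assert ev_f < 5e-3 and ev_c / ev_f > 8.0  # ~16 for exact O(dt^2)
        ea_c99 = fd_err(truth, truth.v, truth.a, q=99.0)
        ea_f99 = fd_err(fine, fine.v, fine.a, q=99.0)
        assert ea_c99 / ea_f99 > 8.0
        assert fd_err(truth, truth.v, truth.a) / fd_err(fine, fine.v, fine.a) > 3.0

    def test_rate_floor_enforced(self, skeleton):
        with pytest.raises(ValueError, match="50"):
            forward_kinematics(skeleton, MotionScript([], 30.0, 0), rate=20.0)


class TestSynthesizeImu:
    def test_static_upright_reads_gravity_reaction(self, skeleton):
        truth = forward_kinematics(skeleton, MotionScript([], 3.0, 0), rate=100.0)
        zero = kg.NoiseSpec(sigma_w=0.0, sigma_a=0.0, sigma_bw_walk=0.0,
                            sigma_ba_walk=0.0, dt=0.01)
        streams, _ = synthesize_imu(truth, zero, seed=0,
                                    init_bias_sigma_a=0.0, init_bias_sigma_w=0.0)
        for s, stream in enumerate(streams):
            np.testing.assert_allclose(stream.gyro, 0, atol=1e-12)
            # specific force in the IMU frame: -R^T g, |.| = 9.81
            np.testing.assert_allclose(
                np.linalg.norm(stream.accel, axis=1), 9.81, atol=1e-9
            )
            np.testing.assert_allclose(
                stream.accel, truth.R[:, s].transpose(0, 2, 1) @ [0, 0, 9.81], atol=1e-9
            )

    def test_gyro_noise_variance_matches_discrete_density(self, skeleton):
        truth = forward_kinematics(skeleton, MotionScript([], 60.0, 0), rate=200.0)
        noise = kg.NoiseSpec(sigma_w=0.005, sigma_a=0.05, sigma_bw_walk=0.0,
                             sigma_ba_walk=0.0)
        streams, _ = synthesize_imu(truth, noise, seed=1,
                                    init_bias_sigma_a=0.0, init_bias_sigma_w=0.0)
        var = np.var(np.concatenate([s.gyro.ravel() for s in streams]))
        assert var == pytest.approx(noise.sigma_w ** 2 / noise.dt, rel=0.05)

    def test_deterministic_given_seed(self, skeleton):
        truth = forward_kinematics(skeleton, MotionScript([], 3.0, 0), rate=100.0)
        noise = kg.NoiseSpec(dt=0.01)
        s1, _ = synthesize_imu(truth, noise, seed=5)
        s2, _ = synthesize_imu(truth, noise, seed=5)
        np.testing.assert_array_equal(s1[3].gyro, s2[3].gyro)
        np.testing.assert_array_equal(s1[3].accel, s2[3].accel)

    def test_bias_random_walk_scale(self, skeleton):
        truth = forward_kinematics(skeleton, MotionScript([], 50.0, 0), rate=100.0)
        noise = kg.NoiseSpec(sigma_w=0.0, sigma_a=0.0, sigma_bw_walk=1e-3,
                             sigma_ba_walk=1e-3, dt=0.01)
        _, tb = synthesize_imu(truth, noise, seed=2,
                               init_bias_sigma_a=0.0, init_bias_sigma_w=0.0)
        # after T seconds the walk variance is sigma^2 * T
        final = tb.biases[-1].ravel()
        assert np.std(final) == pytest.approx(1e-3 * np.sqrt(50.0), rel=0.5)


class TestSoftTissue:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth(skeleton):
        script = script_motion_profile(30.0, seed=1)
        return forward_kinematics(skeleton, script, rate=100.0)

    def test_zero_amplitude_returns_input(self, truth):
        assert perturb_soft_tissue(truth, 0.0, 0.0, 1.0, seed=0) is truth

    def test_joint_center_residual_bounded_by_construction(self, truth, skeleton):
        amp_mm, amp_deg = 5.0, 1.0
        pert = perturb_soft_tissue(truth, amp_mm, amp_deg, 1.0, seed=3)
        s_max = max(np.linalg.norm(v) for v in skeleton.offsets.values())
        bound = 2.0 * (amp_mm * 1e-3 + np.deg2rad(amp_deg) * s_max) * 1.05
        worst = 0.0
        means = []
        for _, A, sA, B, sB in JOINT_SPECS:
            e = (
                np.einsum("kab,b->ka", pert.R[:, A], skeleton.offsets[sA])
                + pert.p[:, A]
                - np.einsum("kab,b->ka", pert.R[:, B], skeleton.offsets[sB])
                - pert.p[:, B]
            )
            worst = max(worst, float(np.linalg.norm(e, axis=1).max()))
            means.append(np.linalg.norm(e.mean(axis=0)))
        assert worst <= bound
        # zero-mean over the trajectory
        assert max(means) < 0.2 * amp_mm * 1e-3

    def test_hinge_vector_cloud_acquires_spread(self, truth, skeleton):
        pert = perturb_soft_tissue(truth, 5.0, 1.0, 1.0, seed=3)
        axis, A, B = HINGE_SPECS[0]
        r = skeleton.axes[axis]
        # during knee motion the perpendicular components spread out
        norms = []
        for k in range(len(truth.t)):
            e = hinge_residual(r, pert.R[k, A], pert.R[k, B],
                               pert.omega[k, A], pert.omega[k, B])
            norms.append(np.linalg.norm(e))
        assert np.std(norms) > 1e-3

    def test_perturbed_truth_remains_self_consistent(self, truth):
        # the perturbation adds its own analytic velocity terms, so the
        # finite-difference error stays at the unperturbed discretization level
        pert = perturb_soft_tissue(truth, 5.0, 1.0, 1.0, seed=3)
        dt = truth.t[1] - truth.t[0]

        def fd_err(tr):
            num = (tr.p[2:] - tr.p[:-2]) / (2 * dt)
            return np.abs(num - tr.v[1:-1]).max()

        assert fd_err(pert) < fd_err(truth) + 1e-3


class TestTruthValuesAndCalibration:
    def test_residuals_vanish_at_truth_for_noise_free_data(self, skeleton):
        script = script_motion_profile(30.0, seed=1)
        truth = forward_kinematics(skeleton, script, rate=100.0)
        noise = kg.NoiseSpec(dt=0.01, decimation=10)
        vals = truth_values(truth, noise)
        kf = np.arange(vals.M) * noise.decimation
        for axis, A, B in HINGE_SPECS:
            e = hinge_residual(vals.axis(axis), vals.R[5, A], vals.R[5, B],
                               vals.w[5, A], vals.w[5, B])
            assert np.linalg.norm(e) < 1e-10
        # anchoring holds
        assert np.linalg.norm(vals.p[0, 0]) < 1e-12
        assert np.linalg.norm(vals.v[0, 0]) < 1e-12
        R00 = vals.R[0, 0]
        assert abs(np.arctan2(R00[1, 0], R00[0, 0])) < 1e-12

    def test_calibrated_angvel_variance_matches_density(self, skeleton):
        script = script_motion_profile(30.0, seed=1)
        truth = forward_kinematics(skeleton, script, rate=100.0)
        noise = kg.NoiseSpec(dt=0.01, decimation=10)
        cal = calibrate_covariances(truth, noise)
        assert cal.cov_angvel[0, 0] == pytest.approx(noise.sigma_w ** 2 / noise.dt, rel=1e-3)
        # perturbation inflates the fitted hinge covariance
        pert = perturb_soft_tissue(truth, 5.0, 1.0, 1.0, seed=3)
        cal_p = calibrate_covariances(pert, noise)
        assert cal_p.cov_hinge[0, 0] > cal.cov_hinge[0, 0]
        assert cal_p.cov_joint[0, 0] > cal.cov_joint[0, 0]
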