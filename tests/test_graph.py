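"""Factor-graph assembly, gauge handling, linearization, and the solver."""

import numpy as np
import pytest

import kinegraph as kg
from kinegraph.graph import (
    SolverConfig,
    Values,
    _Engine,
    add_gauge_priors,
    apply_gauge,
    build_graph,
    estimate_hinge_axis,
    estimate_joint_offsets,
    initialize_values,
    linearize,
    optimize,
    total_error,
)
from kinegraph.manifold import Pose, random_rotation, rot_exp
from kinegraph.synthetic import (
    MotionScript,
    forward_kinematics,
    make_skeleton,
    synthesize_imu,
    truth_values,
)


def _cut_values(vals: Values, M: int) -> Values:
    return Values(
        vals.R[:M].copy(), vals.p[:M].copy(), vals.v[:M].copy(),
        vals.w[:M].copy(), vals.b[:M].copy(), vals.axes.copy(), vals.offsets.copy(),
    )


class TestBuildGraph:
    def test_factor_counts_small_graph(self, tiny_streams, tiny_noise):
        # exactly two keyframe intervals
        n = 2 * tiny_noise.decimation + 1
        streams = [kg.ImuStream(s.t[:n], s.gyro[:n], s.accel[:n]) for s in tiny_streams]
        graph = build_graph(streams, tiny_noise)
        M = graph.M
        assert M == 3
        assert graph.count("preint") == 7 * (M - 1)
        assert graph.count("biaswalk") == 7 * (M - 1)
        assert graph.count("angvel") == 7 * M
        assert graph.count("hinge") == 4 * M
        assert graph.count("joint") == 6 * M
        assert graph.count("axisseg") == 4
        assert graph.count("length") == 5
        assert graph.count("window") == 5
        assert graph.count("discrep") == 2
        assert graph.num_variable_dims == 126 * M + 44

    def test_variable_dimension_scales_with_keyframes(self, tiny_graph):
        assert tiny_graph.num_variable_dims == 126 * tiny_graph.M + 44

    def test_misaligned_streams_rejected(self, tiny_streams, tiny_noise):
        bad = [s for s in tiny_streams]
        s0 = bad[3]
        bad[3] = kg.ImuStream(s0.t + 0.001, s0.gyro, s0.accel)
        with pytest.raises(ValueError, match="misaligned"):
            build_graph(bad, tiny_noise)

    def test_wrong_stream_count_rejected(self, tiny_streams, tiny_noise):
        with pytest.raises(ValueError, match="expected 7"):
            build_graph(tiny_streams[:5], tiny_noise)

    def test_too_short_stream_rejected(self, tiny_streams, tiny_noise):
        short = [kg.ImuStream(s.t[:8], s.gyro[:8], s.accel[:8]) for s in tiny_streams]
        with pytest.raises(ValueError, match="two keyframe"):
            build_graph(short, tiny_noise)


class TestTotalError:
    def test_engine_matches_per_factor_enumeration(self, tiny_graph_anchored, rng):
        vals = initialize_values(tiny_graph_anchored)
        vals = vals.retract(rng.normal(scale=0.05, size=tiny_graph_anchored.num_variable_dims))
        eng = _Engine(tiny_graph_anchored)
        r = eng.residual(vals)
        assert float(r @ r) == pytest.approx(total_error(tiny_graph_anchored, vals), rel=1e-10)

    def test_jacobian_matches_numeric_differentiation(self, tiny_graph_anchored, rng):
        vals = initialize_values(tiny_graph_anchored)
        vals = vals.retract(rng.normal(scale=0.05, size=tiny_graph_anchored.num_variable_dims))
        eng = _Engine(tiny_graph_anchored)
        r0, J = eng.linearize(vals)
        n = tiny_graph_anchored.num_variable_dims
        Jd = J.toarray()
        eps = 1e-6
        for c in rng.choice(n, size=40, replace=False):
            d = np.zeros(n)
            d[c] = eps
            num = (eng.residual(vals.retract(d)) - eng.residual(vals.retract(-d))) / (2 * eps)
            np.testing.assert_allclose(num, Jd[:, c], atol=2e-5)

    def test_nonfinite_values_raise(self, tiny_graph):
        vals = initialize_values(tiny_graph)
        vals.p[3, 2, 0] = np.nan
        with pytest.raises(FloatingPointError, match="non-finite"):
            _Engine(tiny_graph).residual(vals)


class TestGaugeFreedom:
    def _values(self, graph, profile_truth, tiny_noise):
        vals = truth_values(profile_truth, tiny_noise)
        return _cut_values(vals, graph.M)

    def test_unanchored_error_invariant_to_gauge_shifts(
        self, tiny_graph, profile_truth, tiny_noise
    ):
        vals = self._values(tiny_graph, profile_truth, tiny_noise)
        eng = _Engine(tiny_graph)
        r = eng.residual(vals)
        e0 = float(r @ r)
        times = tiny_graph.keyframe_times
        moved = apply_gauge(
            vals, times, dp=np.array([2.0, -1.0, 0.5]), dv=np.array([0.3, 0.1, -0.2]),
            dyaw=1.1,
        )
        r1 = eng.residual(moved)
        e1 = float(r1 @ r1)
        assert abs(e1 - e0) <= 1e-8 * max(e0, 1.0)

    def test_anchored_error_changes_under_gauge_shifts(
        self, tiny_graph_anchored, profile_truth, tiny_noise
    ):
        vals = self._values(tiny_graph_anchored, profile_truth, tiny_noise)
        eng = _Engine(tiny_graph_anchored)
        e0 = float(np.sum(eng.residual(vals) ** 2))
        moved = apply_gauge(vals, tiny_graph_anchored.keyframe_times, dyaw=0.5)
        e1 = float(np.sum(eng.residual(moved) ** 2))
        assert e1 > e0 + 1.0

    def test_yaw_prior_zero_for_identity_orientation(self, tiny_graph_anchored):
        vals = initialize_values(tiny_graph_anchored)
        for f in tiny_graph_anchored.factors:
            if f.category == "prior_yaw":
                e = _Engine(tiny_graph_anchored)._small_residual(f, vals)
                np.testing.assert_allclose(e, 0, atol=1e-12)


class TestInitialization:
    def test_identity_poses_and_nominal_statics(self, tiny_graph):
        vals = initialize_values(tiny_graph)
        assert np.all(vals.R == np.eye(3))
        assert not vals.p.any() and not vals.v.any() and not vals.b.any()
        np.testing.assert_array_equal(vals.axis("r2"), [1.0, 0, 0])

    def test_finite_error_at_initialization(self, tiny_graph_anchored):
        e = total_error(tiny_graph_anchored, initialize_values(tiny_graph_anchored))
        assert np.isfinite(e) and e > 0

    def test_deterministic(self, tiny_graph):
        v1 = initialize_values(tiny_graph)
        v2 = initialize_values(tiny_graph)
        for a, b in ((v1.R, v2.R), (v1.p, v2.p), (v1.axes, v2.axes), (v1.offsets, v2.offsets)):
            np.testing.assert_array_equal(a, b)

    def test_non_unit_nominal_axis_rejected(self, tiny_graph):
        from kinegraph.factors import SkeletonVars

        nominal = SkeletonVars.nominal()
        nominal.axes["r2"] = np.array([1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="unit"):
            initialize_values(tiny_graph, nominal)


class TestOptimize:
    @pytest.fixture(scope="module")
    def solved(self, excited_graph, excited_truth_values):
        # converge tightly so the result is a genuine optimum
        return optimize(
            graph=excited_graph,
            init=excited_truth_values,
            config=SolverConfig(abs_error_tol=1e-9, rel_error_tol=1e-12, max_iterations=300),
        )

    def test_error_nonincreasing_over_accepted_steps(self, solved):
        errors = [
            float(line.split()[3])
            for line in solved.log
            if line.endswith("accepted True")
        ]
        assert all(b <= a for a, b in zip(errors, errors[1:]))
        assert solved.termination in ("abs-tol", "rel-tol", "max-iter")

    def test_rotations_remain_on_manifold(self, solved):
        R = solved.values.R
        RtR = np.swapaxes(R, -1, -2) @ R
        assert np.abs(RtR - np.eye(3)).max() < 1e-9
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_noise_free_data_reaches_tiny_whitened_error(self, solved):
        # ~9 residual units out of ~6000 whitened rows come from the static
        # anthropometric priors (the sampled skeleton deviates from the
        # population means); the per-residual share is tiny
        assert solved.final_error < 15.0

    def test_already_optimal_init_terminates_quickly(self, excited_graph, solved):
        again = optimize(excited_graph, solved.values, SolverConfig())
        assert again.iterations <= 2
        assert again.termination == "abs-tol"

    def test_deterministic_iteration_log(self, excited_graph, excited_truth_values):
        cfg = SolverConfig(max_iterations=5)
        s1 = optimize(excited_graph, excited_truth_values, cfg)
        s2 = optimize(excited_graph, excited_truth_values, cfg)
        assert s1.log == s2.log


class TestStaticNonidentifiability:
    def _static_schur_rank_deficiency(self, graph, vals):
        _, J = linearize(graph, vals)
        Jd = J.toarray()
        nk = graph.num_variable_dims - 44
        Hd = Jd[:, :nk].T @ Jd[:, :nk]
        Hds = Jd[:, :nk].T @ Jd[:, nk:]
        Hs = Jd[:, nk:].T @ Jd[:, nk:]
        S = Hs - Hds.T @ np.linalg.pinv(Hd, rcond=1e-10) @ Hds
        sv = np.linalg.svd(S, compute_uv=False)
        return int(np.sum(sv < 1e-8 * max(sv[0], 1.0)))

    def test_no_motion_leaves_statics_rank_deficient(self, skeleton, tiny_noise):
        script = MotionScript(primitives=[], duration=3.0, seed=0)
        truth = forward_kinematics(skeleton, script, rate=100.0)
        zero = kg.NoiseSpec(sigma_w=0.0, sigma_a=0.0, sigma_bw_walk=0.0,
                            sigma_ba_walk=0.0, dt=0.01, decimation=10)
        streams, truth = synthesize_imu(truth, zero, seed=0,
                                        init_bias_sigma_a=0.0, init_bias_sigma_w=0.0)
        graph = add_gauge_priors(build_graph(streams, tiny_noise))
        vals = truth_values(truth, tiny_noise)
        assert self._static_schur_rank_deficiency(graph, vals) >= 8

    def test_excited_motion_makes_statics_identifiable(
        self, excited_graph, excited_truth_values
    ):
        assert self._static_schur_rank_deficiency(excited_graph, excited_truth_values) == 0


class TestDedicatedEstimators:
    def test_hinge_axis_matches_principal_direction_oracle(self, rng):
        axis = np.array([0.9, 0.1, np.sqrt(1 - 0.82)])
        axis /= np.linalg.norm(axis)
        K = 400
        rates = np.sin(np.linspace(0, 6 * np.pi, K)) * 2.0
        R_A = np.array([random_rotation(rng) for _ in range(K)])
        R_B = np.empty_like(R_A)
        w_A = rng.normal(scale=0.3, size=(K, 3))
        w_B = np.empty_like(w_A)
        for k in range(K):
            R_B[k] = R_A[k] @ rot_exp(rng.normal(size=3))
            # choose w_B so the relative angular velocity is rates[k]*axis
            w_B[k] = np.linalg.solve(R_A[k].T @ R_B[k], w_A[k] + rates[k] * axis)
        est = estimate_hinge_axis(R_A, R_B, w_A, w_B)
        m = np.einsum("kba,kbc,kc->ka", R_A, R_B, w_B) - w_A
        _, V = np.linalg.eigh(m.T @ m)
        oracle = V[:, -1]
        assert abs(abs(est @ oracle)) == pytest.approx(1.0, abs=1e-9)
        assert abs(abs(est @ axis)) == pytest.approx(1.0, abs=1e-9)

    def test_joint_offsets_match_brute_force_normal_equations(self, rng):
        s_A = np.array([0.05, -0.02, 0.2])
        s_B = np.array([-0.03, 0.04, -0.18])
        K = 60
        poses_A, poses_B = [], []
        center = rng.normal(size=3)
        for _ in range(K):
            R_A, R_B = random_rotation(rng), random_rotation(rng)
            p_A = center - R_A @ s_A
            p_B = center - R_B @ s_B
            poses_A.append(Pose(R_A, p_A))
            poses_B.append(Pose(R_B, p_B))
        est_A, est_B = estimate_joint_offsets(poses_A, poses_B)
        # brute-force normal equations assembled factor by factor
        H = np.zeros((6, 6))
        g = np.zeros(6)
        for XA, XB in zip(poses_A, poses_B):
            Jk = np.hstack([XA.rotation, -XB.rotation])
            bk = XB.translation - XA.translation
            H += Jk.T @ Jk
            g += Jk.T @ bk
        ref = np.linalg.solve(H, g)
        np.testing.assert_allclose(np.concatenate([est_A, est_B]), ref, atol=1e-9)
        np.testing.assert_allclose(est_A, s_A, atol=1e-9)
        np.testing.assert_allclose(est_B, s_B, atol=1e-9)
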