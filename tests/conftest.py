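"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

import kinegraph as kg
from kinegraph.graph import add_gauge_priors, build_graph
from kinegraph.synthetic import truth_values


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def skeleton():
    return kg.make_skeleton(seed=1)


@pytest.fixture(scope="session")
def profile_truth(skeleton):
    """Noise-free full-profile truth at a reduced rate (100 Hz, 60 s)."""
    script = kg.script_motion_profile(60.0, seed=1)
    return kg.forward_kinematics(skeleton, script, rate=100.0)


@pytest.fixture(scope="session")
def tiny_noise():
    # 100 Hz, keyframes every 10 samples
    return kg.NoiseSpec(dt=1.0 / 100.0, decimation=10)


@pytest.fixture(scope="session")
def tiny_streams(profile_truth, tiny_noise):
    """Noisy 3-s cut of the profile (M=30): small enough for dense checks."""
    streams, _ = kg.synthesize_imu(profile_truth, tiny_noise, seed=3)
    cut = 300
    return [kg.ImuStream(s.t[:cut], s.gyro[:cut], s.accel[:cut]) for s in streams]


@pytest.fixture()
def tiny_graph(tiny_streams, tiny_noise):
    return build_graph(tiny_streams, tiny_noise)


@pytest.fixture()
def tiny_graph_anchored(tiny_streams, tiny_noise):
    return add_gauge_priors(build_graph(tiny_streams, tiny_noise))


@pytest.fixture(scope="session")
def excited_dataset():
    """Noise-free, fully excited 30-s profile at heavy decimation (M=30):
    every static variable is identifiable and the optimum sits at truth."""
    sk = kg.make_skeleton(seed=2)
    script = kg.script_motion_profile(30.0, seed=2)
    truth = kg.forward_kinematics(sk, script, rate=100.0)
    zero = kg.NoiseSpec(
        sigma_w=0.0, sigma_a=0.0, sigma_bw_walk=0.0, sigma_ba_walk=0.0,
        dt=0.01, decimation=100,
    )
    streams, truth = kg.synthesize_imu(
        truth, zero, seed=2, init_bias_sigma_a=0.0, init_bias_sigma_w=0.0
    )
    noise = kg.NoiseSpec(dt=0.01, decimation=100)
    return sk, truth, streams, noise


@pytest.fixture(scope="module")
def excited_graph(excited_dataset):
    _, _, streams, noise = excited_dataset
    return add_gauge_priors(build_graph(streams, noise))


@pytest.fixture(scope="session")
def excited_truth_values(excited_dataset):
    _, truth, _, noise = excited_dataset
    return truth_values(truth, noise)


@pytest.fixture(scope="session")
def truth_solution(profile_truth, tiny_noise, skeleton):
    """A Solution built directly from ground truth (no optimization)."""
    from kinegraph.graph import Solution

    vals = truth_values(profile_truth, tiny_noise)
    return Solution(
        values=vals,
        skeleton=vals.skeleton(),
        final_error=0.0,
        iterations=0,
        termination="abs-tol",
        keyframe_times=profile_truth.t[:: tiny_noise.decimation],
    )
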