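"""Factor-graph assembly and on-manifold MAP smoothing.

The full posterior over seven IMU trajectories and the static skeleton
variables factors into preintegrated IMU-dynamics constraints, bias
random-walk constraints, per-keyframe angular-velocity constraints, knee
hinge constraints, joint-center constraints, and static anthropometric
priors. The MAP estimate minimizes the sum of squared Mahalanobis residuals
over all factors.

The solver is Levenberg-Marquardt on the product manifold
(SE(3) x R^3 x R^3 x R^6)^(7M) x (S^2)^4 x R^36, with analytic Jacobians
evaluated family-by-family in batched numpy and assembled into one sparse
Jacobian. The normal equations are block-banded in time with a 44-column
"arrow" for the static variables, which are ordered last so a natural-order
sparse LU stays nearly fill-free.

IMU index convention (0-based here, 1-based in file formats): 0 lumbar,
1 right thigh, 2 right shank, 3 right foot, 4 left thigh, 5 left shank,
6 left foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .factors import (
    AXIS_NAMES,
    OFFSET_NAMES,
    AnthroPrior,
    AxisSegmentPrior,
    SkeletonVars,
    axis_segment_angle_residual,
    discrepancy_residual,
    hinge_residual,
    joint_center_residual,
    length_window_derivative,
    length_window_penalty,
    load_anthropometry,
    segment_length_residual,
)
from .imu import (
    BiasState,
    ImuState,
    ImuStream,
    NoiseSpec,
    angvel_residual,
    bias_residual,
    preint_residual,
    preintegrate,
)
from .manifold import (
    Pose,
    hat,
    rot_exp,
    sphere_basis,
    sphere_retract,
)

__all__ = [
    "IMU_NAMES",
    "HINGE_SPECS",
    "JOINT_SPECS",
    "Factor",
    "FactorGraph",
    "SolverConfig",
    "Solution",
    "Values",
    "build_graph",
    "add_gauge_priors",
    "initialize_values",
    "optimize",
    "total_error",
    "linearize",
    "apply_gauge",
    "estimate_hinge_axis",
    "estimate_joint_offsets",
]

N_IMUS = 7
STATE_DIM = 18  # pose 6 + velocity 3 + angular velocity 3 + bias 6
STATIC_DIM = 2 * len(AXIS_NAMES) + 3 * len(OFFSET_NAMES)  # 44

IMU_NAMES = (
    "lumbar",
    "right_thigh",
    "right_shank",
    "right_foot",
    "left_thigh",
    "left_shank",
    "left_foot",
)

# hinge factors: (axis name, frame-A IMU, frame-B IMU); the proximal and
# distal forms of each knee share the same physical axis expressed in the
# two flanking IMU frames
HINGE_SPECS = (
    ("r2", 1, 2),
    ("r3", 2, 1),
    ("r5", 4, 5),
    ("r6", 5, 4),
)

# joint-center factors: (joint, IMU A, offset A, IMU B, offset B)
JOINT_SPECS = (
    ("right_hip", 0, "s1rh", 1, "s2rh"),
    ("right_knee", 1, "s2rk", 2, "s3rk"),
    ("right_ankle", 2, "s3ra", 3, "s4ra"),
    ("left_hip", 0, "s1lh", 4, "s5lh"),
    ("left_knee", 4, "s5lk", 5, "s6lk"),
    ("left_ankle", 5, "s6la", 6, "s7la"),
)

# axis-segment factors: (axis, proximal offset, distal offset, prior key)
AXIS_SEGMENT_SPECS = (
    ("r2", "s2rh", "s2rk", "right_femur"),
    ("r3", "s3rk", "s3ra", "right_tibia"),
    ("r5", "s5lh", "s5lk", "left_femur"),
    ("r6", "s6lk", "s6la", "left_tibia"),
)

# anthropometric length factors: (offset 1, offset 2, prior key)
LENGTH_SPECS = (
    ("s2rh", "s2rk", "femur"),
    ("s3rk", "s3ra", "tibia"),
    ("s5lh", "s5lk", "femur"),
    ("s6lk", "s6la", "tibia"),
    ("s1rh", "s1lh", "pelvis"),
)

# discrepancy factors: (right pair, left pair, prior key)
DISCREPANCY_SPECS = (
    (("s2rh", "s2rk"), ("s5lh", "s5lk"), "femur"),
    (("s3rk", "s3ra"), ("s6lk", "s6la"), "tibia"),
)

_AXIS_INDEX = {name: i for i, name in enumerate(AXIS_NAMES)}
_OFFSET_INDEX = {name: i for i, name in enumerate(OFFSET_NAMES)}


# ---------------------------------------------------------------------------
# batched SO(3) helpers (vectorized counterparts of the manifold primitives)
# ---------------------------------------------------------------------------

def _bhat(v: np.ndarray) -> np.ndarray:
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def _bexp(w: np.ndarray) -> np.ndarray:
    """Batched SO(3) exponential (Rodrigues with Taylor fallback)."""
    w = np.asarray(w, dtype=float)
    t2 = np.sum(w * w, axis=-1)
    t = np.sqrt(t2)
    small = t2 < 1e-14
    ts = np.where(small, 1.0, t)
    a1 = np.where(small, 1.0 - t2 / 6.0, np.sin(ts) / ts)
    a2 = np.where(small, 0.5 - t2 / 24.0, (1.0 - np.cos(ts)) / np.where(small, 1.0, t2))
    W = _bhat(w)
    W2 = W @ W
    return np.eye(3) + a1[..., None, None] * W + a2[..., None, None] * W2


def _blog(R: np.ndarray) -> np.ndarray:
    """Batched SO(3) logarithm; near-pi entries fall back to the scalar path."""
    from .manifold import rot_log

    R = np.asarray(R, dtype=float)
    tr = np.trace(R, axis1=-2, axis2=-1)
    c = np.clip((tr - 1.0) * 0.5, -1.0, 1.0)
    theta = np.arccos(c)
    v = 0.5 * np.stack(
        [
            R[..., 2, 1] - R[..., 1, 2],
            R[..., 0, 2] - R[..., 2, 0],
            R[..., 1, 0] - R[..., 0, 1],
        ],
        axis=-1,
    )
    small = theta < 1e-7
    s = np.where(small, 1.0, np.sin(theta))
    scale = np.where(small, 1.0 + theta ** 2 / 6.0, theta / s)
    out = scale[..., None] * v
    near_pi = np.pi - theta < 1e-4
    if np.any(near_pi):
        idx = np.argwhere(near_pi)
        for ix in idx:
            out[tuple(ix)] = rot_log(R[tuple(ix)])
    return out


def _bJr(w: np.ndarray) -> np.ndarray:
    t2 = np.sum(w * w, axis=-1)
    t = np.sqrt(t2)
    small = t2 < 1e-14
    t2s = np.where(small, 1.0, t2)
    a1 = np.where(small, 0.5 - t2 / 24.0, (1.0 - np.cos(t)) / t2s)
    a2 = np.where(small, 1.0 / 6.0 - t2 / 120.0, (t - np.sin(t)) / (t2s * np.where(small, 1.0, t)))
    W = _bhat(w)
    return np.eye(3) - a1[..., None, None] * W + a2[..., None, None] * (W @ W)


def _bJr_inv(w: np.ndarray) -> np.ndarray:
    t2 = np.sum(w * w, axis=-1)
    t = np.sqrt(t2)
    small = t2 < 1e-14
    ts = np.where(small, 1.0, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        cot_half = np.cos(0.5 * ts) / np.sin(0.5 * ts)
        coeff = np.where(small, 1.0 / 12.0, (1.0 / np.where(small, 1.0, t2)) - 0.5 * cot_half / ts)
    W = _bhat(w)
    return np.eye(3) + 0.5 * W + coeff[..., None, None] * (W @ W)


def _reorthonormalize_fast(R: np.ndarray) -> np.ndarray:
    # one Newton step of the polar projection; keeps drift ~machine epsilon
    RtR = np.swapaxes(R, -1, -2) @ R
    return 1.5 * R - 0.5 * (R @ RtR)


# ---------------------------------------------------------------------------
# variable container
# ---------------------------------------------------------------------------

@dataclass
class Values:
    """A complete assignment of all graph variables.

    Trajectory arrays are indexed ``[keyframe, imu]``; statics are stored in
    the fixed orders of ``AXIS_NAMES`` and ``OFFSET_NAMES``. The tangent
    layout (used by :meth:`retract`) is keyframe-major --
    18 coordinates per IMU state ``(dtheta, dp, dv, dw, db)`` -- followed by
    the 8 axis coordinates and 36 offset coordinates.
    """

    R: np.ndarray  # (M, 7, 3, 3)
    p: np.ndarray  # (M, 7, 3)
    v: np.ndarray  # (M, 7, 3)
    w: np.ndarray  # (M, 7, 3)
    b: np.ndarray  # (M, 7, 6) accelerometer block first
    axes: np.ndarray  # (4, 3)
    offsets: np.ndarray  # (12, 3)

    @property
    def M(self) -> int:
        return self.R.shape[0]

    @property
    def dim(self) -> int:
        return STATE_DIM * N_IMUS * self.M + STATIC_DIM

    @classmethod
    def zeros(cls, M: int) -> "Values":
        return cls(
            R=np.tile(np.eye(3), (M, N_IMUS, 1, 1)),
            p=np.zeros((M, N_IMUS, 3)),
            v=np.zeros((M, N_IMUS, 3)),
            w=np.zeros((M, N_IMUS, 3)),
            b=np.zeros((M, N_IMUS, 6)),
            axes=np.tile(np.array([1.0, 0.0, 0.0]), (len(AXIS_NAMES), 1)),
            offsets=np.zeros((len(OFFSET_NAMES), 3)),
        )

    def copy(self) -> "Values":
        return Values(
            self.R.copy(), self.p.copy(), self.v.copy(), self.w.copy(),
            self.b.copy(), self.axes.copy(), self.offsets.copy(),
        )

    def retract(self, delta: np.ndarray) -> "Values":
        M = self.M
        n_state = STATE_DIM * N_IMUS * M
        d = delta[:n_state].reshape(M, N_IMUS, STATE_DIM)
        R = _reorthonormalize_fast(self.R @ _bexp(d[..., 0:3]))
        p = self.p + d[..., 3:6]
        v = self.v + d[..., 6:9]
        w = self.w + d[..., 9:12]
        b = self.b + d[..., 12:18]
        ds = delta[n_state:]
        axes = np.array(
            [
                sphere_retract(self.axes[i], ds[2 * i : 2 * i + 2])
                for i in range(len(AXIS_NAMES))
            ]
        )
        offsets = self.offsets + ds[2 * len(AXIS_NAMES) :].reshape(-1, 3)
        return Values(R, p, v, w, b, axes, offsets)

    # named accessors ------------------------------------------------------
    def state(self, k: int, s: int) -> ImuState:
        return ImuState(
            Pose(self.R[k, s], self.p[k, s]),
            self.v[k, s],
            self.w[k, s],
            BiasState(self.b[k, s, :3], self.b[k, s, 3:]),
        )

    def axis(self, name: str) -> np.ndarray:
        return self.axes[_AXIS_INDEX[name]]

    def offset(self, name: str) -> np.ndarray:
        return self.offsets[_OFFSET_INDEX[name]]

    def skeleton(self) -> SkeletonVars:
        return SkeletonVars(
            axes={n: self.axes[i].copy() for n, i in _AXIS_INDEX.items()},
            offsets={n: self.offsets[i].copy() for n, i in _OFFSET_INDEX.items()},
        )


def _state_col(M: int, k, s, comp0: int):
    """First tangent column of component ``comp0`` of state (k, s)."""
    return STATE_DIM * (np.asarray(k) * N_IMUS + np.asarray(s)) + comp0


def _axis_col(M: int, name: str) -> int:
    return STATE_DIM * N_IMUS * M + 2 * _AXIS_INDEX[name]


def _offset_col(M: int, name: str) -> int:
    return STATE_DIM * N_IMUS * M + 2 * len(AXIS_NAMES) + 3 * _OFFSET_INDEX[name]


# ---------------------------------------------------------------------------
# graph structure
# ---------------------------------------------------------------------------

@dataclass
class Factor:
    """One probabilistic constraint: a category, variable keys, and data.

    Keys are ``("x", k, s)`` for IMU states and static names for skeleton
    variables. ``data`` holds whatever the residual needs (a preintegrated
    delta, a gyro sample, a prior, ...).
    """

    category: str
    keys: tuple
    data: object = None


@dataclass
class SolverConfig:
    """Levenberg-Marquardt settings.

    Convergence follows the batch-smoothing convention: stop on an absolute
    error change of ``abs_error_tol`` or less, a relative change of
    ``rel_error_tol`` or less, or ``max_iterations``, whichever first.
    """

    abs_error_tol: float = 1e-6
    rel_error_tol: float = 1e-4
    max_iterations: int = 10000
    lm_lambda_init: float = 1e-5
    lm_lambda_factor: float = 10.0
    lm_lambda_max: float = 1e12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abs_error_tol <= 0 or self.rel_error_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FactorGraph:
    """The assembled estimation problem."""

    M: int
    noise: NoiseSpec
    factors: list
    deltas: list  # deltas[i][s]: PreintegratedDelta for interval (i, i+1)
    keyframe_gyro: np.ndarray  # (M, 7, 3) raw gyro sample at each keyframe
    keyframe_times: np.ndarray  # (M,)
    axis_priors: dict
    length_priors: dict
    window_sigma: float = 0.01
    axis_sigma_scale: float = 1.0  # < 1 replicates the static angle priors per keyframe

    @property
    def num_variable_dims(self) -> int:
        return STATE_DIM * N_IMUS * self.M + STATIC_DIM

    def count(self, category: str) -> int:
        return sum(1 for f in self.factors if f.category == category)


def build_graph(
    streams,
    noise: NoiseSpec,
    axis_priors: dict | None = None,
    length_priors: dict | None = None,
    axis_priors_per_keyframe: bool = False,
    window_sigma: float = 0.01,
) -> FactorGraph:
    """Assemble the full seven-IMU factor graph from raw measurement streams.

    Keyframes are placed every ``noise.decimation`` samples; the measurements
    inside each interval are preintegrated at zero linearization bias. For M
    keyframes the graph holds 7(M-1) preintegration factors, 7(M-1) bias
    random-walk factors, 7M angular-velocity factors, 4M hinge factors, 6M
    joint-center factors, 4 axis-segment factors, 5 anthropometric length
    factors, 5 window penalties, and 2 discrepancy factors.

    ``axis_priors_per_keyframe`` recovers a per-keyframe replication of the
    (all-static) axis-segment factors by dividing their sigma by sqrt(M);
    by default they are included once so the prior strength does not grow
    with trajectory length.
    """
    streams = [
        s if isinstance(s, ImuStream) else ImuStream.from_measurements(s)
        for s in streams
    ]
    if len(streams) != N_IMUS:
        raise ValueError(f"expected {N_IMUS} streams, got {len(streams)}")
    N = len(streams[0])
    for i, s in enumerate(streams[1:], start=1):
        if len(s) != N or np.any(np.abs(s.t - streams[0].t) > 1e-6):
            raise ValueError(f"stream {i + 1} timestamps are misaligned with stream 1")
    d = noise.decimation
    if N < 2 * d:
        raise ValueError("streams must span at least two keyframe intervals")
    dt_meas = np.diff(streams[0].t)
    if np.any(np.abs(dt_meas - noise.dt) > 1e-6):
        bad = int(np.argmax(np.abs(dt_meas - noise.dt) > 1e-6))
        raise ValueError(f"non-uniform sample timing at index {bad + 1}")

    M = (N - 1) // d + 1
    kf_samples = np.arange(M) * d
    keyframe_times = streams[0].t[kf_samples]
    keyframe_gyro = np.stack(
        [s.gyro[kf_samples] for s in streams], axis=1
    )  # (M, 7, 3)

    if axis_priors is None or length_priors is None:
        ax_default, len_default = load_anthropometry()
        axis_priors = axis_priors or ax_default
        length_priors = length_priors or len_default

    # preintegrate every interval for every IMU (zero linearization bias)
    zero_bias = BiasState.zero()
    deltas = []
    for i in range(M - 1):
        row = []
        lo, hi = i * d, (i + 1) * d
        for s in streams:
            row.append(
                preintegrate(
                    ImuStream(s.t[lo:hi], s.gyro[lo:hi], s.accel[lo:hi]).measurements(),
                    zero_bias,
                    noise,
                )
            )
        deltas.append(row)

    factors: list[Factor] = []
    for i in range(M - 1):
        for s in range(N_IMUS):
            factors.append(
                Factor("preint", (("x", i, s), ("x", i + 1, s)), deltas[i][s])
            )
    for i in range(M - 1):
        for s in range(N_IMUS):
            factors.append(Factor("biaswalk", (("x", i, s), ("x", i + 1, s)), d * noise.dt))
    for k in range(M):
        for s in range(N_IMUS):
            factors.append(Factor("angvel", (("x", k, s),), keyframe_gyro[k, s]))
    for k in range(M):
        for axis, A, B in HINGE_SPECS:
            factors.append(Factor("hinge", (("x", k, A), ("x", k, B), axis), (axis, A, B)))
    for k in range(M):
        for joint, A, sA, B, sB in JOINT_SPECS:
            factors.append(
                Factor("joint", (("x", k, A), ("x", k, B), sA, sB), (joint, A, sA, B, sB))
            )
    axis_sigma_scale = 1.0 / np.sqrt(M) if axis_priors_per_keyframe else 1.0
    for axis, sp_, sd_, key in AXIS_SEGMENT_SPECS:
        factors.append(Factor("axisseg", (axis, sp_, sd_), axis_priors[key]))
    for s1, s2, key in LENGTH_SPECS:
        factors.append(Factor("length", (s1, s2), length_priors[key]))
    for s1, s2, key in LENGTH_SPECS:
        factors.append(Factor("window", (s1, s2), length_priors[key]))
    for (r1, r2), (l1, l2), key in DISCREPANCY_SPECS:
        factors.append(Factor("discrep", (r1, r2, l1, l2), length_priors[key]))

    return FactorGraph(
        M=M,
        noise=noise,
        factors=factors,
        deltas=deltas,
        keyframe_gyro=keyframe_gyro,
        keyframe_times=keyframe_times,
        axis_priors=axis_priors,
        length_priors=length_priors,
        window_sigma=window_sigma,
        axis_sigma_scale=axis_sigma_scale,
    )


def add_gauge_priors(
    graph: FactorGraph,
    sigma_pos: float = 1e-3,
    sigma_vel: float = 1e-3,
    sigma_yaw: float = 1e-3,
    sigma_bias_a: float = 0.1,
    sigma_bias_w: float = 0.05,
) -> FactorGraph:
    """Anchor the gauge freedoms on the first lumbar keyframe.

    Adds a zero-position, zero-velocity, and zero-heading (1-DOF yaw) prior
    on the lumbar IMU at keyframe 1, plus weak zero priors on every IMU's
    initial bias. Without these, the total error is invariant to global
    translation/velocity/heading shifts and the normal equations are
    singular.
    """
    graph.factors.append(Factor("prior_pos", (("x", 0, 0),), sigma_pos))
    graph.factors.append(Factor("prior_vel", (("x", 0, 0),), sigma_vel))
    graph.factors.append(Factor("prior_yaw", (("x", 0, 0),), sigma_yaw))
    for s in range(N_IMUS):
        graph.factors.append(
            Factor("prior_bias", (("x", 0, s),), (sigma_bias_a, sigma_bias_w))
        )
    return graph


def initialize_values(graph: FactorGraph, nominal: SkeletonVars | None = None) -> Values:
    """Trivial initialization: identity orientations, zeros elsewhere,
    skeleton statics from a nominal alignment."""
    if nominal is None:
        nominal = SkeletonVars.nominal()
    vals = Values.zeros(graph.M)
    for name, i in _AXIS_INDEX.items():
        ax = np.asarray(nominal.axes[name], dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise ValueError(f"nominal axis {name} is not unit norm")
        vals.axes[i] = ax
    for name, i in _OFFSET_INDEX.items():
        vals.offsets[i] = np.asarray(nominal.offsets[name], dtype=float)
    return vals


# ---------------------------------------------------------------------------
# reference (per-factor) evaluation
# ---------------------------------------------------------------------------

def _factor_error(graph: FactorGraph, f: Factor, values: Values) -> float:
    """Squared Mahalanobis norm of one factor, computed with the plain
    per-factor residual operations (the reference path)."""
    noise = graph.noise
    if f.category == "preint":
        (_, i, s), (_, j, _) = f.keys
        r = preint_residual(f.data, values.state(i, s), values.state(j, s), noise)
        return float(r @ np.linalg.solve(f.data.cov, r))
    if f.category == "biaswalk":
        (_, i, s), (_, j, _) = f.keys
        r = bias_residual(
            values.state(i, s).bias, values.state(j, s).bias, noise, f.data, whiten=True
        )
        return float(r @ r)
    if f.category == "angvel":
        (_, k, s) = f.keys[0]
        r = angvel_residual(values.w[k, s], values.b[k, s, 3:], f.data)
        return float(r @ np.linalg.solve(noise.cov_angvel, r))
    if f.category == "hinge":
        axis, A, B = f.data
        k = f.keys[0][1]
        r = hinge_residual(
            values.axis(axis), values.R[k, A], values.R[k, B], values.w[k, A], values.w[k, B]
        )
        return float(r @ np.linalg.solve(noise.cov_hinge, r))
    if f.category == "joint":
        _, A, sA, B, sB = f.data
        k = f.keys[0][1]
        r = joint_center_residual(
            Pose(values.R[k, A], values.p[k, A]),
            values.offset(sA),
            Pose(values.R[k, B], values.p[k, B]),
            values.offset(sB),
        )
        return float(r @ np.linalg.solve(noise.cov_joint, r))
    if f.category == "axisseg":
        axis, sp_, sd_ = f.keys
        prior: AxisSegmentPrior = f.data
        e = axis_segment_angle_residual(
            values.axis(axis), values.offset(sp_), values.offset(sd_), prior
        )
        return (e / (prior.sigma * graph.axis_sigma_scale)) ** 2
    if f.category == "length":
        s1, s2 = f.keys
        prior: AnthroPrior = f.data
        e = segment_length_residual(values.offset(s1), values.offset(s2), prior)
        return (e / prior.sigma_L) ** 2
    if f.category == "window":
        s1, s2 = f.keys
        prior = f.data
        x = float(np.linalg.norm(values.offset(s1) - values.offset(s2)))
        return (length_window_penalty(x, prior) / graph.window_sigma) ** 2
    if f.category == "discrep":
        r1, r2, l1, l2 = f.keys
        prior = f.data
        e = discrepancy_residual(
            values.offset(r1), values.offset(r2), values.offset(l1), values.offset(l2)
        )
        return (e / prior.sigma_D) ** 2
    if f.category == "prior_pos":
        (_, k, s) = f.keys[0]
        return float(values.p[k, s] @ values.p[k, s]) / f.data ** 2
    if f.category == "prior_vel":
        (_, k, s) = f.keys[0]
        return float(values.v[k, s] @ values.v[k, s]) / f.data ** 2
    if f.category == "prior_yaw":
        (_, k, s) = f.keys[0]
        R = values.R[k, s]
        yaw = np.arctan2(R[1, 0], R[0, 0])
        return (yaw / f.data) ** 2
    if f.category == "prior_bias":
        (_, k, s) = f.keys[0]
        sa, sw = f.data
        r = np.concatenate([values.b[k, s, :3] / sa, values.b[k, s, 3:] / sw])
        return float(r @ r)
    raise KeyError(f.category)


def total_error(graph: FactorGraph, values: Values) -> float:
    """Sum over factors of the squared Mahalanobis residual norm."""
    return sum(_factor_error(graph, f, values) for f in graph.factors)


# ---------------------------------------------------------------------------
# batched linearization engine
# ---------------------------------------------------------------------------

def _whitener(cov: np.ndarray) -> np.ndarray:
    """W with W^T W = cov^-1 (inverse Cholesky factor)."""
    return np.linalg.inv(np.linalg.cholesky(cov))


class _Engine:
    """Batched residual/Jacobian evaluation for one graph.

    The sparsity pattern (COO rows/cols) is fixed at construction; each
    linearization fills a preallocated data vector family by family.
    """

    def __init__(self, graph: FactorGraph):
        self.graph = graph
        g = graph
        M, noise = g.M, g.noise
        self.M = M
        self.ncols = g.num_variable_dims
        dT = noise.decimation * noise.dt

        # --- preintegration family ---
        F1 = N_IMUS * (M - 1)
        idx_i = np.repeat(np.arange(M - 1), N_IMUS)
        idx_s = np.tile(np.arange(N_IMUS), M - 1)
        self.pi_i, self.pi_s = idx_i, idx_s
        dl = [g.deltas[i][s] for i, s in zip(idx_i, idx_s)]
        self.pi_dR = np.array([d.dR for d in dl])
        self.pi_dv = np.array([d.dv for d in dl])
        self.pi_dp = np.array([d.dp for d in dl])
        self.pi_JRbw = np.array([d.J_R_bw for d in dl])
        self.pi_Jvbw = np.array([d.J_v_bw for d in dl])
        self.pi_Jvba = np.array([d.J_v_ba for d in dl])
        self.pi_Jpbw = np.array([d.J_p_bw for d in dl])
        self.pi_Jpba = np.array([d.J_p_ba for d in dl])
        self.pi_linb = np.array([d.lin_bias.vector() for d in dl])
        self.pi_W = np.array([_whitener(d.cov) for d in dl])
        self.pi_dT = dT

        # --- bias random walk (constant Jacobian) ---
        sd_walk = np.concatenate(
            [
                np.full(3, noise.sigma_ba_walk * np.sqrt(dT)),
                np.full(3, noise.sigma_bw_walk * np.sqrt(dT)),
            ]
        )
        self.bw_inv_sd = 1.0 / sd_walk

        # --- angular velocity ---
        self.Wg = _whitener(noise.cov_angvel)
        self.av_meas = g.keyframe_gyro.reshape(M * N_IMUS, 3)

        # --- hinge ---
        self.Wk = _whitener(noise.cov_hinge)
        self.hi_k = np.repeat(np.arange(M), len(HINGE_SPECS))
        self.hi_A = np.tile(np.array([h[1] for h in HINGE_SPECS]), M)
        self.hi_B = np.tile(np.array([h[2] for h in HINGE_SPECS]), M)
        self.hi_axis = np.tile(
            np.array([_AXIS_INDEX[h[0]] for h in HINGE_SPECS]), M
        )

        # --- joint centers ---
        self.Wj = _whitener(noise.cov_joint)
        self.jc_k = np.repeat(np.arange(M), len(JOINT_SPECS))
        self.jc_A = np.tile(np.array([j[1] for j in JOINT_SPECS]), M)
        self.jc_B = np.tile(np.array([j[3] for j in JOINT_SPECS]), M)
        self.jc_sA = np.tile(np.array([_OFFSET_INDEX[j[2]] for j in JOINT_SPECS]), M)
        self.jc_sB = np.tile(np.array([_OFFSET_INDEX[j[4]] for j in JOINT_SPECS]), M)

        # --- small static/prior factors handled per-factor ---
        self.small_factors = [
            f
            for f in g.factors
            if f.category
            in (
                "axisseg", "length", "window", "discrep",
                "prior_pos", "prior_vel", "prior_yaw", "prior_bias",
            )
        ]

        self._build_pattern()

    # -- sparsity pattern ---------------------------------------------------
    def _block_cols(self, starts, width):
        """(F, width) column indices from (F,) block starts."""
        return starts[:, None] + np.arange(width)[None, :]

    def _build_pattern(self):
        M = self.M
        rows_list, cols_list = [], []
        row0 = 0

        def add_family(res_dim, col_blocks):
            nonlocal row0
            F = col_blocks[0].shape[0]
            cols = np.concatenate(col_blocks, axis=1)  # (F, ncols_per_factor)
            nc = cols.shape[1]
            r = row0 + np.arange(F * res_dim).reshape(F, res_dim)
            rows_list.append(np.repeat(r, nc, axis=1).reshape(F, res_dim, nc).ravel())
            cols_list.append(np.broadcast_to(cols[:, None, :], (F, res_dim, nc)).ravel())
            row0 += F * res_dim
            return (row0 - F * res_dim, row0)

        sc = lambda k, s, c: _state_col(M, k, s, c)

        # preint: rows 9; cols theta_i, p_i, v_i, b_i, theta_j, p_j, v_j
        i, s = self.pi_i, self.pi_s
        self.rows_preint = add_family(
            9,
            [
                self._block_cols(sc(i, s, 0), 3),
                self._block_cols(sc(i, s, 3), 3),
                self._block_cols(sc(i, s, 6), 3),
                self._block_cols(sc(i, s, 12), 6),
                self._block_cols(sc(i + 1, s, 0), 3),
                self._block_cols(sc(i + 1, s, 3), 3),
                self._block_cols(sc(i + 1, s, 6), 3),
            ],
        )
        # biaswalk: rows 6; cols b_i, b_j
        self.rows_biaswalk = add_family(
            6,
            [
                self._block_cols(sc(i, s, 12), 6),
                self._block_cols(sc(i + 1, s, 12), 6),
            ],
        )
        # angvel: rows 3; cols w, b_gyro
        kk = np.repeat(np.arange(M), N_IMUS)
        ss = np.tile(np.arange(N_IMUS), M)
        self.rows_angvel = add_family(
            3,
            [
                self._block_cols(sc(kk, ss, 9), 3),
                self._block_cols(sc(kk, ss, 15), 3),
            ],
        )
        # hinge: rows 3; cols theta_A, w_A, theta_B, w_B, axis(2)
        hk, hA, hB = self.hi_k, self.hi_A, self.hi_B
        axis_starts = STATE_DIM * N_IMUS * M + 2 * self.hi_axis
        self.rows_hinge = add_family(
            3,
            [
                self._block_cols(sc(hk, hA, 0), 3),
                self._block_cols(sc(hk, hA, 9), 3),
                self._block_cols(sc(hk, hB, 0), 3),
                self._block_cols(sc(hk, hB, 9), 3),
                self._block_cols(axis_starts, 2),
            ],
        )
        # joint: rows 3; cols theta_A, p_A, theta_B, p_B, s_A, s_B
        jk, jA, jB = self.jc_k, self.jc_A, self.jc_B
        off0 = STATE_DIM * N_IMUS * M + 2 * len(AXIS_NAMES)
        self.rows_joint = add_family(
            3,
            [
                self._block_cols(sc(jk, jA, 0), 3),
                self._block_cols(sc(jk, jA, 3), 3),
                self._block_cols(sc(jk, jB, 0), 3),
                self._block_cols(sc(jk, jB, 3), 3),
                self._block_cols(off0 + 3 * self.jc_sA, 3),
                self._block_cols(off0 + 3 * self.jc_sB, 3),
            ],
        )

        # small factors: enumerate their (rows, cols) one by one
        self.small_meta = []
        for f in self.small_factors:
            cols = self._small_cols(f)
            dim = self._small_dim(f)
            r = row0 + np.arange(dim)
            rows_list.append(np.repeat(r, len(cols)))
            cols_list.append(np.tile(cols, dim))
            self.small_meta.append((row0, dim, cols))
            row0 += dim

        self.nrows = row0
        self.rows = np.concatenate(rows_list)
        self.cols = np.concatenate(cols_list)

    def _small_dim(self, f: Factor) -> int:
        return {
            "axisseg": 1, "length": 1, "window": 1, "discrep": 1,
            "prior_pos": 3, "prior_vel": 3, "prior_yaw": 1, "prior_bias": 6,
        }[f.category]

    def _small_cols(self, f: Factor) -> np.ndarray:
        M = self.M
        if f.category == "axisseg":
            axis, sp_, sd_ = f.keys
            return np.concatenate(
                [
                    _axis_col(M, axis) + np.arange(2),
                    _offset_col(M, sp_) + np.arange(3),
                    _offset_col(M, sd_) + np.arange(3),
                ]
            )
        if f.category in ("length", "window"):
            s1, s2 = f.keys
            return np.concatenate(
                [_offset_col(M, s1) + np.arange(3), _offset_col(M, s2) + np.arange(3)]
            )
        if f.category == "discrep":
            return np.concatenate(
                [_offset_col(M, n) + np.arange(3) for n in f.keys]
            )
        (_, k, s) = f.keys[0]
        base = {"prior_pos": 3, "prior_vel": 6, "prior_yaw": 0, "prior_bias": 12}[
            f.category
        ]
        width = {"prior_pos": 3, "prior_vel": 3, "prior_yaw": 3, "prior_bias": 6}[
            f.category
        ]
        return _state_col(M, k, s, base) + np.arange(width)

    # -- evaluation ---------------------------------------------------------
    def _preint_terms(self, vals: Values):
        i, s = self.pi_i, self.pi_s
        R_i = vals.R[i, s]
        R_j = vals.R[i + 1, s]
        RiT = np.swapaxes(R_i, 1, 2)
        C = RiT @ R_j
        db = vals.b[i, s] - self.pi_linb
        dba, dbw = db[:, :3], db[:, 3:]
        corr_vec = np.einsum("fab,fb->fa", self.pi_JRbw, dbw)
        dR_corr = self.pi_dR @ _bexp(corr_vec)
        r_R = _blog(np.swapaxes(dR_corr, 1, 2) @ C)
        dT = self.pi_dT
        g = self.graph.noise.gravity
        u_v = vals.v[i + 1, s] - vals.v[i, s] - g * dT
        u_p = (
            vals.p[i + 1, s] - vals.p[i, s] - vals.v[i, s] * dT - 0.5 * g * dT * dT
        )
        Ri_uv = np.einsum("fba,fb->fa", R_i, u_v)  # R_i^T u
        Ri_up = np.einsum("fba,fb->fa", R_i, u_p)
        r_v = Ri_uv - (
            self.pi_dv
            + np.einsum("fab,fb->fa", self.pi_Jvbw, dbw)
            + np.einsum("fab,fb->fa", self.pi_Jvba, dba)
        )
        r_p = Ri_up - (
            self.pi_dp
            + np.einsum("fab,fb->fa", self.pi_Jpbw, dbw)
            + np.einsum("fab,fb->fa", self.pi_Jpba, dba)
        )
        return RiT, C, corr_vec, r_R, r_v, r_p, Ri_uv, Ri_up

    def residual(self, vals: Values) -> np.ndarray:
        r = np.empty(self.nrows)
        g = self.graph

        # preint
        _, _, _, r_R, r_v, r_p, _, _ = self._preint_terms(vals)
        raw = np.concatenate([r_R, r_v, r_p], axis=1)
        lo, hi = self.rows_preint
        r[lo:hi] = np.einsum("fab,fb->fa", self.pi_W, raw).ravel()

        # biaswalk
        i, s = self.pi_i, self.pi_s
        lo, hi = self.rows_biaswalk
        r[lo:hi] = ((vals.b[i + 1, s] - vals.b[i, s]) * self.bw_inv_sd).ravel()

        # angvel
        lo, hi = self.rows_angvel
        raw = vals.w.reshape(-1, 3) + vals.b[:, :, 3:].reshape(-1, 3) - self.av_meas
        r[lo:hi] = (raw @ self.Wg.T).ravel()

        # hinge
        lo, hi = self.rows_hinge
        m, _, _ = self._hinge_m(vals)
        ax = vals.axes[self.hi_axis]
        mr = np.sum(m * ax, axis=1)
        raw = m - mr[:, None] * ax
        r[lo:hi] = (raw @ self.Wk.T).ravel()

        # joint
        lo, hi = self.rows_joint
        k, A, B = self.jc_k, self.jc_A, self.jc_B
        sA = vals.offsets[self.jc_sA]
        sB = vals.offsets[self.jc_sB]
        raw = (
            np.einsum("fab,fb->fa", vals.R[k, A], sA)
            + vals.p[k, A]
            - np.einsum("fab,fb->fa", vals.R[k, B], sB)
            - vals.p[k, B]
        )
        r[lo:hi] = (raw @ self.Wj.T).ravel()

        for f, (row0, dim, _) in zip(self.small_factors, self.small_meta):
            r[row0 : row0 + dim] = self._small_residual(f, vals)

        if not np.all(np.isfinite(r)):
            bad = int(np.argmin(np.isfinite(r)))
            raise FloatingPointError(
                f"non-finite residual at whitened row {bad}"
            )
        return r

    def _hinge_m(self, vals: Values):
        k, A, B = self.hi_k, self.hi_A, self.hi_B
        RAB = np.swapaxes(vals.R[k, A], 1, 2) @ vals.R[k, B]
        u = np.einsum("fab,fb->fa", RAB, vals.w[k, B])
        m = u - vals.w[k, A]
        return m, u, RAB

    def _small_residual(self, f: Factor, vals: Values) -> np.ndarray:
        g = self.graph
        if f.category == "axisseg":
            axis, sp_, sd_ = f.keys
            prior = f.data
            e = axis_segment_angle_residual(
                vals.axis(axis), vals.offset(sp_), vals.offset(sd_), prior
            )
            return np.array([e / (prior.sigma * g.axis_sigma_scale)])
        if f.category == "length":
            s1, s2 = f.keys
            e = segment_length_residual(vals.offset(s1), vals.offset(s2), f.data)
            return np.array([e / f.data.sigma_L])
        if f.category == "window":
            s1, s2 = f.keys
            x = float(np.linalg.norm(vals.offset(s1) - vals.offset(s2)))
            return np.array([length_window_penalty(x, f.data) / g.window_sigma])
        if f.category == "discrep":
            r1, r2, l1, l2 = f.keys
            e = discrepancy_residual(
                vals.offset(r1), vals.offset(r2), vals.offset(l1), vals.offset(l2)
            )
            return np.array([e / f.data.sigma_D])
        (_, k, s) = f.keys[0]
        if f.category == "prior_pos":
            return vals.p[k, s] / f.data
        if f.category == "prior_vel":
            return vals.v[k, s] / f.data
        if f.category == "prior_yaw":
            R = vals.R[k, s]
            return np.array([np.arctan2(R[1, 0], R[0, 0]) / f.data])
        if f.category == "prior_bias":
            sa, sw = f.data
            return np.concatenate([vals.b[k, s, :3] / sa, vals.b[k, s, 3:] / sw])
        raise KeyError(f.category)

    def _small_jacobian(self, f: Factor, vals: Values) -> np.ndarray:
        """Dense (dim, len(cols)) whitened Jacobian of one small factor."""
        g = self.graph
        if f.category == "axisseg":
            axis, sp_, sd_ = f.keys
            prior = f.data
            r_ = vals.axis(axis)
            d = vals.offset(sp_) - vals.offset(sd_)
            n = np.linalg.norm(d)
            u = d / n
            c = float(np.clip(r_ @ u, -1.0, 1.0))
            dedc = 1.0 / np.sqrt(max(1.0 - c * c, 1e-12))
            dcdr = u @ sphere_basis(r_)  # (2,)
            dcds = (r_ @ (np.eye(3) - np.outer(u, u))) / n  # (3,)
            J = np.concatenate([dedc * dcdr, dedc * dcds, -dedc * dcds])
            return J[None, :] / (prior.sigma * g.axis_sigma_scale)
        if f.category == "length":
            s1, s2 = f.keys
            d = vals.offset(s1) - vals.offset(s2)
            u = d / np.linalg.norm(d)
            return np.concatenate([u, -u])[None, :] / f.data.sigma_L
        if f.category == "window":
            s1, s2 = f.keys
            d = vals.offset(s1) - vals.offset(s2)
            x = float(np.linalg.norm(d))
            if x == 0.0:
                return np.zeros((1, 6))
            u = d / x
            fp = length_window_derivative(x, f.data)
            return (fp * np.concatenate([u, -u]))[None, :] / g.window_sigma
        if f.category == "discrep":
            r1, r2, l1, l2 = f.keys
            dr = vals.offset(r1) - vals.offset(r2)
            dl_ = vals.offset(l1) - vals.offset(l2)
            ur = dr / np.linalg.norm(dr)
            ul = dl_ / np.linalg.norm(dl_)
            return np.concatenate([ur, -ur, -ul, ul])[None, :] / f.data.sigma_D
        (_, k, s) = f.keys[0]
        if f.category in ("prior_pos", "prior_vel"):
            return np.eye(3) / f.data
        if f.category == "prior_yaw":
            R = vals.R[k, s]
            den = R[0, 0] ** 2 + R[1, 0] ** 2
            # d yaw / d theta for right perturbation R <- R exp(theta^)
            dR10 = np.array([0.0, -R[1, 2], R[1, 1]])
            dR00 = np.array([0.0, -R[0, 2], R[0, 1]])
            dyaw = (R[0, 0] * dR10 - R[1, 0] * dR00) / den
            return dyaw[None, :] / f.data
        if f.category == "prior_bias":
            sa, sw = f.data
            return np.diag(np.concatenate([np.full(3, 1 / sa), np.full(3, 1 / sw)]))
        raise KeyError(f.category)

    def linearize(self, vals: Values):
        """Whitened residual vector and sparse Jacobian at ``vals``."""
        data_parts = []
        r = np.empty(self.nrows)

        # ---- preint ----
        RiT, C, corr_vec, r_R, r_v, r_p, Ri_uv, Ri_up = self._preint_terms(vals)
        lo, hi = self.rows_preint
        raw = np.concatenate([r_R, r_v, r_p], axis=1)
        r[lo:hi] = np.einsum("fab,fb->fa", self.pi_W, raw).ravel()

        F1 = len(self.pi_i)
        Jri = _bJr_inv(r_R)
        Er = _bexp(r_R)
        Jr_corr = _bJr(corr_vec)
        J = np.zeros((F1, 9, 24))
        # columns: theta_i(0:3) p_i(3:6) v_i(6:9) b_i(9:15) theta_j(15:18)
        #          p_j(18:21) v_j(21:24)
        J[:, 0:3, 0:3] = -Jri @ np.swapaxes(C, 1, 2)
        J[:, 0:3, 15:18] = Jri
        J[:, 0:3, 12:15] = -Jri @ np.swapaxes(Er, 1, 2) @ Jr_corr @ self.pi_JRbw
        J[:, 3:6, 0:3] = _bhat(Ri_uv)
        J[:, 3:6, 6:9] = -RiT
        J[:, 3:6, 21:24] = RiT
        J[:, 3:6, 9:12] = -self.pi_Jvba
        J[:, 3:6, 12:15] = -self.pi_Jvbw
        J[:, 6:9, 0:3] = _bhat(Ri_up)
        J[:, 6:9, 3:6] = -RiT
        J[:, 6:9, 18:21] = RiT
        J[:, 6:9, 6:9] = -RiT * self.pi_dT
        J[:, 6:9, 9:12] = -self.pi_Jpba
        J[:, 6:9, 12:15] = -self.pi_Jpbw
        data_parts.append((self.pi_W @ J).ravel())

        # ---- biaswalk (constant) ----
        i, s = self.pi_i, self.pi_s
        lo, hi = self.rows_biaswalk
        r[lo:hi] = ((vals.b[i + 1, s] - vals.b[i, s]) * self.bw_inv_sd).ravel()
        Jbw = np.zeros((len(i), 6, 12))
        Jbw[:, :, 0:6] = -np.diag(self.bw_inv_sd)
        Jbw[:, :, 6:12] = np.diag(self.bw_inv_sd)
        data_parts.append(Jbw.ravel())

        # ---- angvel (constant) ----
        lo, hi = self.rows_angvel
        raw = vals.w.reshape(-1, 3) + vals.b[:, :, 3:].reshape(-1, 3) - self.av_meas
        r[lo:hi] = (raw @ self.Wg.T).ravel()
        F2 = self.M * N_IMUS
        Jav = np.zeros((F2, 3, 6))
        Jav[:, :, 0:3] = self.Wg
        Jav[:, :, 3:6] = self.Wg
        data_parts.append(Jav.ravel())

        # ---- hinge ----
        lo, hi = self.rows_hinge
        m, u, RAB = self._hinge_m(vals)
        ax = vals.axes[self.hi_axis]
        mr = np.sum(m * ax, axis=1)
        raw = m - mr[:, None] * ax
        r[lo:hi] = (raw @ self.Wk.T).ravel()
        F3 = len(self.hi_k)
        P = np.eye(3)[None] - ax[:, :, None] * ax[:, None, :]
        Jh = np.zeros((F3, 3, 14))
        wB = vals.w[self.hi_k, self.hi_B]
        Jh[:, :, 0:3] = P @ _bhat(u)
        Jh[:, :, 3:6] = -P
        Jh[:, :, 6:9] = -(P @ RAB) @ _bhat(wB)
        Jh[:, :, 9:12] = P @ RAB
        dedr = -mr[:, None, None] * np.eye(3)[None] - ax[:, :, None] * m[:, None, :]
        basis = np.array([sphere_basis(a) for a in vals.axes])  # (4,3,2)
        Jh[:, :, 12:14] = dedr @ basis[self.hi_axis]
        data_parts.append((self.Wk[None] @ Jh).ravel())

        # ---- joint ----
        lo, hi = self.rows_joint
        k, A, B = self.jc_k, self.jc_A, self.jc_B
        sA = vals.offsets[self.jc_sA]
        sB = vals.offsets[self.jc_sB]
        RA = vals.R[k, A]
        RB = vals.R[k, B]
        raw = (
            np.einsum("fab,fb->fa", RA, sA)
            + vals.p[k, A]
            - np.einsum("fab,fb->fa", RB, sB)
            - vals.p[k, B]
        )
        r[lo:hi] = (raw @ self.Wj.T).ravel()
        F4 = len(k)
        Jj = np.zeros((F4, 3, 18))
        Jj[:, :, 0:3] = -RA @ _bhat(sA)
        Jj[:, :, 3:6] = np.eye(3)
        Jj[:, :, 6:9] = RB @ _bhat(sB)
        Jj[:, :, 9:12] = -np.eye(3)
        Jj[:, :, 12:15] = RA
        Jj[:, :, 15:18] = -RB
        data_parts.append((self.Wj[None] @ Jj).ravel())

        # ---- small factors ----
        for f, (row0, dim, cols) in zip(self.small_factors, self.small_meta):
            r[row0 : row0 + dim] = self._small_residual(f, vals)
            data_parts.append(self._small_jacobian(f, vals).ravel())

        data = np.concatenate(data_parts)
        Jsp = sp.csr_matrix(
            (data, (self.rows, self.cols)), shape=(self.nrows, self.ncols)
        )
        if not np.all(np.isfinite(r)):
            bad = int(np.argmin(np.isfinite(r)))
            raise FloatingPointError(f"non-finite residual at whitened row {bad}")
        return r, Jsp


def linearize(graph: FactorGraph, values: Values):
    """Whitened residual and sparse Jacobian of the whole graph."""
    return _Engine(graph).linearize(values)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """Optimizer output: the MAP assignment plus bookkeeping."""

    values: Values
    skeleton: SkeletonVars
    final_error: float
    iterations: int
    termination: str
    log: list = field(default_factory=list)
    keyframe_times: np.ndarray | None = None
    # on-disk orientation representation (w,x,y,z), kept by the reader so an
    # unmodified solution re-serializes byte-identically
    quaternions: np.ndarray | None = None

    def state(self, k: int, s: int) -> ImuState:
        return self.values.state(k, s)


def _solve_damped(JtJ: sp.csc_matrix, diag: np.ndarray, lam: float, g: np.ndarray):
    """Solve (JtJ + lam*diag) x = -g.

    The variable ordering is keyframe-major with the 44 static coordinates
    last, so the damped Hessian is banded (inter-keyframe bandwidth ~134)
    bordered by a dense static arrow. Small systems go through a dense
    solve; large ones through banded Cholesky on the trajectory block and a
    dense Schur complement on the statics, with a sparse-LU fallback if the
    banded factorization loses positive definiteness numerically.
    """
    n = JtJ.shape[0]
    H = (JtJ + sp.diags(lam * diag)).tocsc()
    if n <= 1500:
        return np.linalg.solve(H.toarray(), -g)
    nk = n - STATIC_DIM
    try:
        import scipy.linalg as sla

        T = H[:nk, :nk].tocoo()
        mask = T.row >= T.col
        rows, cols, data = T.row[mask], T.col[mask], T.data[mask]
        kd = int((rows - cols).max())
        ab = np.zeros((kd + 1, nk))
        ab[rows - cols, cols] = data
        cb = sla.cholesky_banded(ab, lower=True)
        U = H[:nk, nk:].toarray()
        B = np.concatenate([(-g[:nk])[:, None], U], axis=1)
        Y = sla.cho_solve_banded((cb, True), B)
        y, Z = Y[:, 0], Y[:, 1:]
        S = H[nk:, nk:].toarray() - U.T @ Z
        x2 = np.linalg.solve(S, -g[nk:] - U.T @ y)
        x1 = y - Z @ x2
        return np.concatenate([x1, x2])
    except np.linalg.LinAlgError:
        pass
    lu = spla.splu(H)
    return lu.solve(-g)


def optimize(
    graph: FactorGraph, init: Values, config: SolverConfig | None = None
) -> Solution:
    """Levenberg-Marquardt minimization of the total whitened squared error.

    The damping term scales the diagonal of the Gauss-Newton Hessian
    (multiplicative damping), multiplied by ``lm_lambda_factor`` on a
    rejected step and divided by it on an accepted one. Error is
    nonincreasing across accepted steps; the run terminates on the absolute
    or relative error-change tolerance, on iteration count, or when the
    damping exceeds ``lm_lambda_max`` ("stalled", reported as abs-tol since
    no further error reduction is achievable).
    """
    if config is None:
        config = SolverConfig()
    engine = _Engine(graph)
    vals = init.copy()
    r = engine.residual(vals)
    error = float(r @ r)
    lam = config.lm_lambda_init
    log: list[str] = []
    termination = "max-iter"
    it = 0
    while it < config.max_iterations:
        it += 1
        _, J = engine.linearize(vals)
        JtJ = (J.T @ J).tocsc()
        diag = np.maximum(JtJ.diagonal(), 1e-10)
        g = J.T @ engine.residual(vals)
        accepted = False
        while True:
            delta = _solve_damped(JtJ, diag, lam, g)
            cand = vals.retract(delta)
            try:
                r_new = engine.residual(cand)
            except FloatingPointError:
                r_new = None
            e_new = float(r_new @ r_new) if r_new is not None else np.inf
            step_norm = float(np.linalg.norm(delta))
            change = error - e_new
            if e_new < error:
                accepted = True
                log.append(
                    f"iter {it} error {e_new:.12g} lambda {lam:.3g} "
                    f"step {step_norm:.6g} accepted True"
                )
                vals = cand
                prev_error, error = error, e_new
                lam = max(lam / config.lm_lambda_factor, 1e-12)
                if prev_error - error <= config.abs_error_tol:
                    termination = "abs-tol"
                elif prev_error > 0 and (prev_error - error) / prev_error <= config.rel_error_tol:
                    termination = "rel-tol"
                break
            log.append(
                f"iter {it} error {e_new:.12g} lambda {lam:.3g} "
                f"step {step_norm:.6g} accepted False"
            )
            if np.isfinite(change) and abs(change) <= config.abs_error_tol:
                termination = "abs-tol"
                break
            lam *= config.lm_lambda_factor
            if lam > config.lm_lambda_max:
                termination = "abs-tol"
                break
        if accepted and termination == "max-iter":
            continue
        if termination != "max-iter":
            break
    # exact re-orthonormalization of all rotations on the way out
    U, _, Vt = np.linalg.svd(vals.R)
    det = np.linalg.det(U @ Vt)
    D = np.tile(np.eye(3), U.shape[:2] + (1, 1))
    D[..., 2, 2] = np.sign(det)
    vals.R = U @ D @ Vt
    return Solution(
        values=vals,
        skeleton=vals.skeleton(),
        final_error=error,
        iterations=it,
        termination=termination,
        log=log,
        keyframe_times=graph.keyframe_times,
    )


# ---------------------------------------------------------------------------
# gauge helpers and small dedicated solvers
# ---------------------------------------------------------------------------

def apply_gauge(
    values: Values,
    times: np.ndarray,
    dp: np.ndarray | None = None,
    dv: np.ndarray | None = None,
    dyaw: float = 0.0,
) -> Values:
    """Apply a global gauge shift: constant position offset, constant
    velocity offset (with the matching time-linear position drift), and a
    heading rotation about gravity."""
    out = values.copy()
    G = rot_exp(np.array([0.0, 0.0, dyaw]))
    out.R = G[None, None] @ out.R
    out.p = np.einsum("ab,ksb->ksa", G, out.p)
    out.v = np.einsum("ab,ksb->ksa", G, out.v)
    if dp is not None:
        out.p = out.p + np.asarray(dp)[None, None, :]
    if dv is not None:
        dv = np.asarray(dv)
        out.v = out.v + dv[None, None, :]
        out.p = out.p + times[:, None, None] * dv[None, None, :]
    return out


def estimate_hinge_axis(
    R_A: np.ndarray,
    R_B: np.ndarray,
    omega_A: np.ndarray,
    omega_B: np.ndarray,
    init: np.ndarray | None = None,
    max_iterations: int = 100,
    tol: float = 1e-14,
) -> np.ndarray:
    """Estimate a static hinge axis in frame A from paired orientation and
    angular-velocity sequences, by Gauss-Newton on the sphere over the hinge
    residuals. The sign of the result is arbitrary (resolved post hoc)."""
    m = np.einsum("kba,kbc,kc->ka", R_A, R_B, omega_B) - omega_A
    if init is None:
        # principal direction of the relative angular-velocity cloud
        _, V = np.linalg.eigh(m.T @ m)
        r = V[:, -1]
    else:
        r = np.asarray(init, dtype=float)
        r = r / np.linalg.norm(r)
    for _ in range(max_iterations):
        B = sphere_basis(r)
        mr = m @ r
        e = m - mr[:, None] * r  # (K, 3)
        Jr_amb = -mr[:, None, None] * np.eye(3)[None] - r[None, :, None] * m[:, None, :]
        J = (Jr_amb @ B).reshape(-1, 2)
        g = J.T @ e.ravel()
        H = J.T @ J + 1e-12 * np.eye(2)
        delta = np.linalg.solve(H, -g)
        r = sphere_retract(r, delta)
        if float(delta @ delta) < tol:
            break
    return r


def estimate_joint_offsets(poses_A, poses_B):
    """Estimate the static IMU-to-joint-center offsets (s_A, s_B) for two
    IMUs flanking a ball joint, from their pose trajectories.

    Solves the linear least-squares system stacking, for every sample,
    ``R_A s_A - R_B s_B = p_B - p_A`` (the joint-center residual set to
    zero). Identifiable only when both IMUs rotate through multiple DOF
    relative to the joint.
    """
    RA = np.array([X.rotation for X in poses_A])
    RB = np.array([X.rotation for X in poses_B])
    pA = np.array([X.translation for X in poses_A])
    pB = np.array([X.translation for X in poses_B])
    K = len(RA)
    A = np.zeros((3 * K, 6))
    A[:, 0:3] = RA.reshape(-1, 3)
    A[:, 3:6] = -RB.reshape(-1, 3)
    rhs = (pB - pA).ravel()
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return sol[:3], sol[3:]
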