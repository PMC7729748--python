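"""IMU measurement model, integration, and keyframe preintegration.

The gyroscope and accelerometer measure, in the sensor body frame B,

    gyro(t)  = omega(t) + b_w(t) + v_w(t)
    accel(t) = R_B^N(t)^T (a^N(t) - g) + b_a(t) + v_a(t)

with slowly varying random-walk biases ``b`` and white noise ``v`` whose
continuous-time densities are ``sigma_w`` (rad/s/sqrt(Hz)) and ``sigma_a``
(m/s^2/sqrt(Hz)); the discrete per-sample noise covariance is the density
squared divided by the sample period.

The first-order Euler kinematic update (one sample, bias held fixed) is

    R <- R exp((gyro - b_w) dt)
    v <- v + g dt + R (accel - b_a) dt
    p <- p + v dt + 1/2 g dt^2 + 1/2 R (accel - b_a) dt^2

All measurements between two keyframes are compounded into a single
gravity-free relative-motion constraint (:class:`PreintegratedDelta`) with a
propagated 9x9 covariance and first-order bias-correction Jacobians, so that
states need only be estimated at the keyframe rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .manifold import Pose, hat, rot_exp, rot_log, so3_right_jacobian, so3_right_jacobian_inv

__all__ = [
    "ImuMeasurement",
    "ImuStream",
    "BiasState",
    "ImuState",
    "NoiseSpec",
    "PreintegratedDelta",
    "integrate_step",
    "preintegrate",
    "preint_residual",
    "bias_residual",
    "angvel_residual",
]

GRAVITY = np.array([0.0, 0.0, -9.81])  # navigation frame, z up


@dataclass
class ImuStream:
    """A full measurement sequence for one IMU, as columnar arrays."""

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if not (len(self.t) == len(self.gyro) == len(self.accel)):
            raise ValueError("stream arrays must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("stream timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def measurements(self) -> list:
        return [
            ImuMeasurement(float(self.t[i]), self.gyro[i], self.accel[i])
            for i in range(len(self.t))
        ]

    @classmethod
    def from_measurements(cls, measurements) -> "ImuStream":
        ms = list(measurements)
        return cls(
            np.array([m.t for m in ms]),
            np.array([m.gyro for m in ms]),
            np.array([m.accel for m in ms]),
        )


@dataclass
class ImuMeasurement:
    """One IMU sample: time (s), gyro (rad/s), accel (m/s^2)."""

    t: float
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)


@dataclass
class BiasState:
    """Accelerometer bias (m/s^2) and gyroscope bias (rad/s)."""

    b_a: np.ndarray
    b_w: np.ndarray

    def __post_init__(self) -> None:
        self.b_a = np.asarray(self.b_a, dtype=float)
        self.b_w = np.asarray(self.b_w, dtype=float)

    @classmethod
    def zero(cls) -> "BiasState":
        return cls(np.zeros(3), np.zeros(3))

    def vector(self) -> np.ndarray:
        """Stacked 6-vector, accelerometer block first."""
        return np.concatenate([self.b_a, self.b_w])


@dataclass
class ImuState:
    """Per-keyframe IMU state: pose, velocity, angular velocity, bias."""

    pose: Pose
    velocity: np.ndarray
    angvel: np.ndarray
    bias: BiasState

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.angvel = np.asarray(self.angvel, dtype=float)

    @classmethod
    def identity(cls) -> "ImuState":
        return cls(Pose.identity(), np.zeros(3), np.zeros(3), BiasState.zero())


@dataclass
class NoiseSpec:
    """Noise densities, factor covariances, gravity, and timing.

    ``sigma_w``/``sigma_a`` are continuous white-noise densities; the bias
    random-walk densities are in rad/s^2/sqrt(Hz) and m/s^3/sqrt(Hz).
    ``cov_angvel`` (Sigma_g), ``cov_hinge`` (Sigma_K) and ``cov_joint``
    (Sigma_j) whiten the angular-velocity, hinge, and joint-center residuals.
    """

    sigma_w: float = 0.005
    sigma_a: float = 0.05
    sigma_bw_walk: float = 1e-4
    sigma_ba_walk: float = 1e-4
    cov_angvel: np.ndarray = field(default_factory=lambda: (0.005 ** 2) * np.eye(3))
    cov_hinge: np.ndarray = field(default_factory=lambda: (0.05 ** 2) * np.eye(3))
    cov_joint: np.ndarray = field(default_factory=lambda: (0.01 ** 2) * np.eye(3))
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    dt: float = 1.0 / 200.0
    decimation: int = 20

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        self.cov_angvel = np.asarray(self.cov_angvel, dtype=float)
        self.cov_hinge = np.asarray(self.cov_hinge, dtype=float)
        self.cov_joint = np.asarray(self.cov_joint, dtype=float)
        if self.dt <= 0:
            raise ValueError("sample period dt must be positive")
        if self.decimation < 1:
            raise ValueError("decimation must be >= 1")
        for name in ("cov_angvel", "cov_hinge", "cov_joint"):
            C = getattr(self, name)
            if not np.allclose(C, C.T) or np.any(np.linalg.eigvalsh(C) <= 0):
                raise ValueError(f"{name} must be symmetric positive definite")

    @property
    def gyro_discrete_var(self) -> float:
        return self.sigma_w ** 2 / self.dt

    @property
    def accel_discrete_var(self) -> float:
        return self.sigma_a ** 2 / self.dt


@dataclass
class PreintegratedDelta:
    """Compound relative-motion constraint over one keyframe interval.

    ``dR``, ``dv``, ``dp`` are the gravity-free motion increments expressed
    in the frame of the opening keyframe, linearized at ``lin_bias``.
    ``cov`` is the 9x9 covariance over (rotation, velocity, position) errors;
    the ``J_*`` blocks are first-order sensitivities to bias deviations.
    """

    dR: np.ndarray
    dv: np.ndarray
    dp: np.ndarray
    dT: float
    lin_bias: BiasState
    cov: np.ndarray
    J_R_bw: np.ndarray
    J_v_bw: np.ndarray
    J_v_ba: np.ndarray
    J_p_bw: np.ndarray
    J_p_ba: np.ndarray
    count: int


def integrate_step(state: ImuState, meas: ImuMeasurement, noise: NoiseSpec) -> ImuState:
    """Advance an IMU state by one sample with the Euler kinematic model."""
    dt = noise.dt
    R = state.pose.rotation
    w = meas.gyro - state.bias.b_w
    a = meas.accel - state.bias.b_a
    Ra = R @ a
    v_new = state.velocity + noise.gravity * dt + Ra * dt
    p_new = (
        state.pose.translation
        + state.velocity * dt
        + 0.5 * noise.gravity * dt * dt
        + 0.5 * Ra * dt * dt
    )
    R_new = R @ rot_exp(w * dt)
    return ImuState(Pose(R_new, p_new), v_new, w, state.bias)


def preintegrate(
    measurements, lin_bias: BiasState, noise: NoiseSpec
) -> PreintegratedDelta:
    """Compound a window of IMU samples into a single relative constraint.

    The increments satisfy, for true states at the window's ends and in the
    absence of noise,

        dR = R_i^T R_j
        dv = R_i^T (v_j - v_i - g dT)
        dp = R_i^T (p_j - p_i - v_i dT - 1/2 g dT^2)

    The covariance is propagated to first order from the white-noise
    densities; gravity does not enter the increments at all (it is
    reintroduced by :func:`preint_residual`).
    """
    measurements = list(measurements)
    if len(measurements) == 0:
        raise ValueError("preintegrate requires at least one measurement")
    dt = noise.dt
    times = np.array([m.t for m in measurements])
    if len(times) > 1:
        gaps = np.diff(times)
        bad = np.nonzero(np.abs(gaps - dt) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform timestamps at measurement index {int(bad[0]) + 1}"
            )

    dR = np.eye(3)
    dv = np.zeros(3)
    dp = np.zeros(3)
    cov = np.zeros((9, 9))
    J_R_bw = np.zeros((3, 3))
    J_v_bw = np.zeros((3, 3))
    J_v_ba = np.zeros((3, 3))
    J_p_bw = np.zeros((3, 3))
    J_p_ba = np.zeros((3, 3))

    var_w = noise.gyro_discrete_var
    var_a = noise.accel_discrete_var

    for m in measurements:
        w = m.gyro - lin_bias.b_w
        a = m.accel - lin_bias.b_a
        wdt = w * dt
        dRk = rot_exp(wdt)
        Jr = so3_right_jacobian(wdt)
        a_hat = hat(a)
        dRa = dR @ a_hat

        # covariance propagation, state order (dphi, dv, dp)
        A = np.eye(9)
        A[0:3, 0:3] = dRk.T
        A[3:6, 0:3] = -dRa * dt
        A[6:9, 0:3] = -0.5 * dRa * dt * dt
        A[6:9, 3:6] = np.eye(3) * dt
        Bg = np.zeros((9, 3))
        Bg[0:3, :] = Jr * dt
        Ba = np.zeros((9, 3))
        Ba[3:6, :] = dR * dt
        Ba[6:9, :] = 0.5 * dR * dt * dt
        cov = A @ cov @ A.T + var_w * (Bg @ Bg.T) + var_a * (Ba @ Ba.T)

        # bias Jacobians (position first: uses current velocity Jacobians)
        J_p_bw = J_p_bw + J_v_bw * dt - 0.5 * dRa @ J_R_bw * dt * dt
        J_p_ba = J_p_ba + J_v_ba * dt - 0.5 * dR * dt * dt
        J_v_bw = J_v_bw - dRa @ J_R_bw * dt
        J_v_ba = J_v_ba - dR * dt
        J_R_bw = dRk.T @ J_R_bw - Jr * dt

        # increments
        dp = dp + dv * dt + 0.5 * dR @ a * dt * dt
        dv = dv + dR @ a * dt
        dR = dR @ dRk

    return PreintegratedDelta(
        dR=dR,
        dv=dv,
        dp=dp,
        dT=len(measurements) * dt,
        lin_bias=BiasState(lin_bias.b_a.copy(), lin_bias.b_w.copy()),
        cov=cov,
        J_R_bw=J_R_bw,
        J_v_bw=J_v_bw,
        J_v_ba=J_v_ba,
        J_p_bw=J_p_bw,
        J_p_ba=J_p_ba,
        count=len(measurements),
    )


def predict(state_i: ImuState, delta: PreintegratedDelta, noise: NoiseSpec) -> ImuState:
    """Predict the state at the closing keyframe from the opening one."""
    R_i = state_i.pose.rotation
    dT = delta.dT
    g = noise.gravity
    dbw = state_i.bias.b_w - delta.lin_bias.b_w
    dba = state_i.bias.b_a - delta.lin_bias.b_a
    dR = delta.dR @ rot_exp(delta.J_R_bw @ dbw)
    dv = delta.dv + delta.J_v_bw @ dbw + delta.J_v_ba @ dba
    dp = delta.dp + delta.J_p_bw @ dbw + delta.J_p_ba @ dba
    R_j = R_i @ dR
    v_j = state_i.velocity + g * dT + R_i @ dv
    p_j = (
        state_i.pose.translation
        + state_i.velocity * dT
        + 0.5 * g * dT * dT
        + R_i @ dp
    )
    return ImuState(Pose(R_j, p_j), v_j, state_i.angvel, state_i.bias)


def preint_residual(
    delta: PreintegratedDelta,
    state_i: ImuState,
    state_j: ImuState,
    noise: NoiseSpec,
    whiten: bool = False,
) -> np.ndarray:
    """9-vector residual of the preintegrated relative-motion constraint.

    Zero when the two states are exactly consistent with the bias-corrected
    increments and gravity. Ordered (rotation, velocity, position).
    """
    R_i = state_i.pose.rotation
    R_j = state_j.pose.rotation
    g = noise.gravity
    dT = delta.dT
    dbw = state_i.bias.b_w - delta.lin_bias.b_w
    dba = state_i.bias.b_a - delta.lin_bias.b_a

    dR_corr = delta.dR @ rot_exp(delta.J_R_bw @ dbw)
    r_R = rot_log(dR_corr.T @ (R_i.T @ R_j))
    r_v = R_i.T @ (state_j.velocity - state_i.velocity - g * dT) - (
        delta.dv + delta.J_v_bw @ dbw + delta.J_v_ba @ dba
    )
    r_p = R_i.T @ (
        state_j.pose.translation
        - state_i.pose.translation
        - state_i.velocity * dT
        - 0.5 * g * dT * dT
    ) - (delta.dp + delta.J_p_bw @ dbw + delta.J_p_ba @ dba)
    r = np.concatenate([r_R, r_v, r_p])
    if whiten:
        L = np.linalg.cholesky(delta.cov + 1e-16 * np.eye(9))
        r = np.linalg.solve(L, r)
    return r


def compose_deltas(
    d1: PreintegratedDelta, d2: PreintegratedDelta
) -> PreintegratedDelta:
    """Compose two consecutive preintegrated windows (shared linearization bias).

    Only the motion increments and duration are composed; the covariance of
    the result is not propagated (use :func:`preintegrate` over the joined
    window when the covariance matters).
    """
    dR = d1.dR @ d2.dR
    dv = d1.dv + d1.dR @ d2.dv
    dp = d1.dp + d1.dv * d2.dT + d1.dR @ d2.dp
    return PreintegratedDelta(
        dR=dR,
        dv=dv,
        dp=dp,
        dT=d1.dT + d2.dT,
        lin_bias=d1.lin_bias,
        cov=np.zeros((9, 9)),
        J_R_bw=np.zeros((3, 3)),
        J_v_bw=np.zeros((3, 3)),
        J_v_ba=np.zeros((3, 3)),
        J_p_bw=np.zeros((3, 3)),
        J_p_ba=np.zeros((3, 3)),
        count=d1.count + d2.count,
    )


def bias_residual(
    bias_i: BiasState,
    bias_j: BiasState,
    noise: NoiseSpec | None = None,
    dT: float = 1.0,
    whiten: bool = False,
) -> np.ndarray:
    """Random-walk residual ``b_j - b_i`` (accel block first).

    When whitened, the covariance is the walk density squared times the
    interval, so a fixed bias difference scales as ``1/sqrt(dT)``.
    """
    r = np.concatenate([bias_j.b_a - bias_i.b_a, bias_j.b_w - bias_i.b_w])
    if whiten:
        sd = np.concatenate(
            [
                np.full(3, noise.sigma_ba_walk * np.sqrt(dT)),
                np.full(3, noise.sigma_bw_walk * np.sqrt(dT)),
            ]
        )
        r = r / sd
    return r


def angvel_residual(
    omega_hat: np.ndarray, b_w: np.ndarray, omega_meas: np.ndarray
) -> np.ndarray:
    """Residual tying the estimated angular velocity to the keyframe gyro sample."""
    return np.asarray(omega_hat) + np.asarray(b_w) - np.asarray(omega_meas)
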