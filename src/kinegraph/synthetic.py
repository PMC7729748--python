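"""Ground-truth lower-body kinematic chain simulator.

Generates exact pose / velocity / angular-velocity / acceleration
trajectories for the seven body-worn IMUs (lumbar, thighs, shanks, feet) of
a subject performing a calibration-style motion profile that excites every
lower-body degree of freedom, then corrupts ideal measurements with white
noise and random-walk biases to produce synthetic gyroscope and
accelerometer streams with known ground truth.

The chain is pelvis -> (ball hip) -> femur -> (hinge knee) -> tibia ->
(ball ankle) -> foot, per side. Segment frames are the anatomical frames
(z proximal, y anterior, x to the subject's right; identity = upright
standing). Joint-angle trajectories are C^2 polynomial pulses and windowed
sinusoids, so angular velocities and accelerations exist in closed form and
the emitted truth is exactly self-consistent: joint-center coherence holds
to machine precision and the relative angular velocity across each knee is
exactly parallel to the true hinge axis.

Knee hinge geometry: the axis is tilted in the femur's x-z plane so that
its angle to the femoral proximal direction matches the population value,
and the tibia carries a constant neutral rotation about the anterior axis
so the same physical axis makes the (different) population angle with the
tibial proximal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import _bexp  # batched SO(3) exponential
from .imu import ImuStream, NoiseSpec
from .manifold import rot_exp

__all__ = [
    "SkeletonTruth",
    "MotionPrimitive",
    "MotionScript",
    "TruthTrajectory",
    "make_skeleton",
    "script_motion_profile",
    "forward_kinematics",
    "synthesize_imu",
    "perturb_soft_tissue",
    "truth_values",
    "calibrate_covariances",
]

# IMU order: lumbar, right thigh, right shank, right foot, left thigh,
# left shank, left foot (matches the estimator's convention)
_IMU_SEGMENTS = (
    "pelvis", "right_femur", "right_tibia", "right_foot",
    "left_femur", "left_tibia", "left_foot",
)


# ---------------------------------------------------------------------------
# C^2 scalar curves
# ---------------------------------------------------------------------------

def _smootherstep(x):
    """s(x) = 6x^5 - 15x^4 + 10x^3 on [0,1]; s', s'' vanish at both ends."""
    x = np.clip(x, 0.0, 1.0)
    s = x ** 3 * (10.0 + x * (-15.0 + 6.0 * x))
    ds = 30.0 * x ** 2 * (x - 1.0) ** 2
    dds = 60.0 * x * (2.0 * x - 1.0) * (x - 1.0)
    return s, ds, dds


def _pulse(t, t0, dur, amp):
    """One C^2 out-and-back bump: 0 -> amp -> 0 over [t0, t0+dur]."""
    u = (t - t0) / dur
    inside = (u > 0.0) & (u < 1.0)
    f = np.zeros_like(t)
    fd = np.zeros_like(t)
    fdd = np.zeros_like(t)
    x = np.where(u < 0.5, 2.0 * u, 2.0 * (1.0 - u))
    sgn = np.where(u < 0.5, 1.0, -1.0)
    s, ds, dds = _smootherstep(x)
    scale = 2.0 / dur
    f[inside] = (amp * s)[inside]
    fd[inside] = (amp * ds * sgn * scale)[inside]
    fdd[inside] = (amp * dds * scale ** 2)[inside]
    return f, fd, fdd


def _wavelet(t, t0, dur, amp, cycles, phase=0.0, ramp=0.2):
    """C^2-windowed sinusoid: amp * w(u) * sin(2*pi*cycles*u + phase)."""
    u = (t - t0) / dur
    inside = (u > 0.0) & (u < 1.0)
    # window: smootherstep up over [0, ramp], down over [1-ramp, 1]
    w_up, dw_up, ddw_up = _smootherstep(u / ramp)
    w_dn, dw_dn, ddw_dn = _smootherstep((1.0 - u) / ramp)
    w = w_up * w_dn
    dw = (dw_up / ramp) * w_dn - w_up * (dw_dn / ramp)
    ddw = (
        (ddw_up / ramp ** 2) * w_dn
        - 2.0 * (dw_up / ramp) * (dw_dn / ramp)
        + w_up * (ddw_dn / ramp ** 2)
    )
    om = 2.0 * np.pi * cycles
    arg = om * u + phase
    sn, cs = np.sin(arg), np.cos(arg)
    g = w * sn
    dg = dw * sn + w * om * cs
    ddg = ddw * sn + 2.0 * dw * om * cs - w * om ** 2 * sn
    scale = 1.0 / dur
    f = np.where(inside, amp * g, 0.0)
    fd = np.where(inside, amp * dg * scale, 0.0)
    fdd = np.where(inside, amp * ddg * scale ** 2, 0.0)
    return f, fd, fdd


class _Curve:
    """Sum of C^2 primitives; evaluates (f, f', f'') on a time grid."""

    def __init__(self):
        self.terms = []

    def add(self, kind, t0, dur, amp, cycles=1, phase=0.0):
        self.terms.append((kind, t0, dur, amp, cycles, phase))
        return self

    def eval(self, t):
        f = np.zeros_like(t)
        fd = np.zeros_like(t)
        fdd = np.zeros_like(t)
        for kind, t0, dur, amp, cycles, phase in self.terms:
            if kind == "pulse":
                a, b, c = _pulse(t, t0, dur, amp)
            else:
                a, b, c = _wavelet(t, t0, dur, amp, cycles, phase)
            f += a
            fd += b
            fdd += c
        return f, fd, fdd


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

@dataclass
class SkeletonTruth:
    """Ground-truth skeleton geometry and IMU mounting.

    Lengths in metres; mounts map IMU index -> (R_mount, u_mount) where
    ``R_mount`` columns are the IMU axes in the segment frame and
    ``u_mount`` is the IMU position from the segment's proximal joint
    center (origin). ``axes`` / ``offsets`` are the true static variables
    expressed in each IMU's own frame; ``axis_angles_deg`` records the
    sampled knee-axis-to-segment angles.
    """

    femur_length: float
    tibia_length: float
    pelvis_width: float
    mounts: dict
    axes: dict
    offsets: dict
    axis_angles_deg: dict
    knee_axis_femur: dict  # side -> axis in femur anatomical frame
    knee_neutral_rot: dict  # side -> constant femur->tibia neutral rotation
    lumbar_height: float = 1.0

    def to_dict(self) -> dict:
        return {
            "femur_length": self.femur_length,
            "tibia_length": self.tibia_length,
            "pelvis_width": self.pelvis_width,
            "lumbar_height": self.lumbar_height,
            "axis_angles_deg": self.axis_angles_deg,
            "axes": {k: list(v) for k, v in self.axes.items()},
            "offsets": {k: list(v) for k, v in self.offsets.items()},
            "mounts": {
                str(k): {"R": [list(r) for r in R], "u": list(u)}
                for k, (R, u) in self.mounts.items()
            },
            "knee_axis_femur": {k: list(v) for k, v in self.knee_axis_femur.items()},
            "knee_neutral_rot": {
                k: [list(r) for r in R] for k, R in self.knee_neutral_rot.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonTruth":
        return cls(
            femur_length=d["femur_length"],
            tibia_length=d["tibia_length"],
            pelvis_width=d["pelvis_width"],
            lumbar_height=d["lumbar_height"],
            axis_angles_deg=d["axis_angles_deg"],
            axes={k: np.array(v) for k, v in d["axes"].items()},
            offsets={k: np.array(v) for k, v in d["offsets"].items()},
            mounts={
                int(k): (np.array(v["R"]), np.array(v["u"]))
                for k, v in d["mounts"].items()
            },
            knee_axis_femur={k: np.array(v) for k, v in d["knee_axis_femur"].items()},
            knee_neutral_rot={
                k: np.array(v) for k, v in d["knee_neutral_rot"].items()
            },
        )


def _truncated_normal(rng, mu, sigma, lo, hi):
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mu, lo, hi))


def make_skeleton(config: dict | None = None, seed: int = 0) -> SkeletonTruth:
    """Sample a ground-truth skeleton from the population priors.

    Segment lengths are drawn from the anthropometric distributions and
    rejected outside the hard windows; knee-axis-to-segment angles are drawn
    from their population distributions truncated at 2.5 sigma. IMU mounting
    poses are randomized: orientation tilted up to ``mount_tilt_deg``
    (default 20) from the nominal segment alignment, position varied along
    the segment and around its circumference.
    """
    cfg = {
        "mount_tilt_deg": 20.0,
        "mount_pos_jitter": 0.02,
        # scales the spread of the sampled axis-segment angles about their
        # population means (0 pins them at the means)
        "axis_angle_sigma_scale": 1.0,
    }
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)

    L_f = _truncated_normal(rng, 0.394, 0.030, 0.326, 0.480)
    L_t = _truncated_normal(rng, 0.411, 0.026, 0.344, 0.479)
    W = _truncated_normal(rng, 0.187, 0.009, 0.120, 0.409)

    asc = cfg["axis_angle_sigma_scale"]
    ang = {
        "right_femur": _truncated_normal(rng, 84.0, 2.4 * asc, 84.0 - 6.0 * asc, 84.0 + 6.0 * asc),
        "right_tibia": _truncated_normal(rng, 92.0, 1.2 * asc, 92.0 - 3.0 * asc, 92.0 + 3.0 * asc),
        "left_femur": _truncated_normal(rng, 96.0, 2.4 * asc, 96.0 - 6.0 * asc, 96.0 + 6.0 * asc),
        "left_tibia": _truncated_normal(rng, 88.0, 1.2 * asc, 88.0 - 3.0 * asc, 88.0 + 3.0 * asc),
    }

    knee_axis_femur = {}
    knee_neutral_rot = {}
    for side in ("right", "left"):
        a_f = np.deg2rad(ang[f"{side}_femur"])
        a_t = np.deg2rad(ang[f"{side}_tibia"])
        axis = np.array([np.sin(a_f), 0.0, np.cos(a_f)])
        gamma = a_f - a_t  # tibia neutral tilt about the anterior axis
        knee_axis_femur[side] = axis
        knee_neutral_rot[side] = rot_exp(np.array([0.0, gamma, 0.0]))

    # mounting poses (R columns = IMU axes in segment frame; u from origin)
    tilt = np.deg2rad(cfg["mount_tilt_deg"])
    jit = cfg["mount_pos_jitter"]

    def mount(u_nominal):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rot_exp(axis * rng.uniform(0.0, tilt))
        u = np.asarray(u_nominal) + rng.uniform(-jit, jit, size=3)
        return R, u

    mounts = {
        0: mount([0.0, -0.09, 0.10]),                       # lumbar on sacrum
        1: mount([0.06, 0.0, -0.5 * L_f]),                  # right thigh, lateral
        2: mount([0.05, 0.0, -0.5 * L_t]),                  # right shank
        3: mount([0.0, 0.07, -0.03]),                       # right foot dorsum
        4: mount([-0.06, 0.0, -0.5 * L_f]),                 # left thigh
        5: mount([-0.05, 0.0, -0.5 * L_t]),                 # left shank
        6: mount([0.0, 0.07, -0.03]),                       # left foot
    }

    # joint positions in each segment frame (origin = proximal joint)
    hips = {"right": np.array([W / 2.0, 0.0, 0.0]), "left": np.array([-W / 2.0, 0.0, 0.0])}
    knee_in_femur = np.array([0.0, 0.0, -L_f])
    ankle_in_tibia = np.array([0.0, 0.0, -L_t])

    def s_of(imu, point_seg):
        R, u = mounts[imu]
        return R.T @ (np.asarray(point_seg) - u)

    offsets = {
        "s1rh": s_of(0, hips["right"]),
        "s1lh": s_of(0, hips["left"]),
        "s2rh": s_of(1, [0.0, 0.0, 0.0]),
        "s2rk": s_of(1, knee_in_femur),
        "s3rk": s_of(2, [0.0, 0.0, 0.0]),
        "s3ra": s_of(2, ankle_in_tibia),
        "s4ra": s_of(3, [0.0, 0.0, 0.0]),
        "s5lh": s_of(4, [0.0, 0.0, 0.0]),
        "s5lk": s_of(4, knee_in_femur),
        "s6lk": s_of(5, [0.0, 0.0, 0.0]),
        "s6la": s_of(5, ankle_in_tibia),
        "s7la": s_of(6, [0.0, 0.0, 0.0]),
    }
    axes = {
        "r2": mounts[1][0].T @ knee_axis_femur["right"],
        "r3": mounts[2][0].T @ (knee_neutral_rot["right"].T @ knee_axis_femur["right"]),
        "r5": mounts[4][0].T @ knee_axis_femur["left"],
        "r6": mounts[5][0].T @ (knee_neutral_rot["left"].T @ knee_axis_femur["left"]),
    }
    return SkeletonTruth(
        femur_length=L_f,
        tibia_length=L_t,
        pelvis_width=W,
        mounts=mounts,
        axes=axes,
        offsets=offsets,
        axis_angles_deg=ang,
        knee_axis_femur=knee_axis_femur,
        knee_neutral_rot=knee_neutral_rot,
    )


# ---------------------------------------------------------------------------
# motion script
# ---------------------------------------------------------------------------

@dataclass
class MotionPrimitive:
    joint: str
    dof: str
    amplitude: float  # degrees (or metres for pelvis position sway)
    reps: int
    t0: float
    duration: float
    kind: str = "pulse"  # pulse | wavelet
    phase: float = 0.0


@dataclass
class MotionScript:
    """Ordered calibration-motion primitives with total duration and seed."""

    primitives: list
    duration: float
    seed: int

    def __post_init__(self) -> None:
        for p in self.primitives:
            if "knee" in p.joint and abs(p.amplitude) > 150.0:
                raise ValueError("knee flexion amplitude exceeds 150 degrees")


def script_motion_profile(duration: float = 60.0, seed: int = 0) -> MotionScript:
    """The default calibration motion profile.

    Ordered as: ankle flexion cycles and foot circles (right then left),
    knee flexion swings of at least 90 degrees (right then left), hip
    flexion / abduction / internal-external rotation (right then left),
    then torso bend, twist, and side-to-side bend; three repetitions each.
    A small 6-DOF pelvis sway runs throughout so every accelerometer sees
    nontrivial specific force. Deterministic for a fixed seed (amplitudes
    are jittered +/-10%).
    """
    if duration < 30.0:
        raise ValueError("motion profile requires at least 30 s")
    rng = np.random.default_rng(seed)
    j = lambda a: float(a * rng.uniform(0.9, 1.1))

    prims: list[MotionPrimitive] = []
    # slot layout fractions (sums to 1)
    frac = {"ankle": 0.06, "knee": 0.09, "hip": 0.07, "torso": 0.16}
    t = 0.0

    def slot(width):
        nonlocal t
        t0 = t
        t += width
        return t0, width

    for side in ("right", "left"):
        t0, w = slot(frac["ankle"] * duration)
        prims.append(MotionPrimitive(f"{side}_ankle", "flexion", j(25.0), 3, t0, w))
        t0, w = slot(frac["ankle"] * duration)
        prims.append(
            MotionPrimitive(f"{side}_ankle", "flexion", j(18.0), 3, t0, w, "wavelet", 0.0)
        )
        prims.append(
            MotionPrimitive(
                f"{side}_ankle", "eversion", j(14.0), 3, t0, w, "wavelet", 0.5 * np.pi
            )
        )
    for side in ("right", "left"):
        t0, w = slot(frac["knee"] * duration)
        prims.append(MotionPrimitive(f"{side}_knee", "flexion", -j(100.0), 3, t0, w))
    for side in ("right", "left"):
        sgn = 1.0 if side == "right" else -1.0
        t0, w = slot(frac["hip"] * duration)
        prims.append(MotionPrimitive(f"{side}_hip", "flexion", j(70.0), 3, t0, w))
        t0, w = slot(frac["hip"] * duration)
        prims.append(MotionPrimitive(f"{side}_hip", "abduction", -sgn * j(40.0), 3, t0, w))
        t0, w = slot(frac["hip"] * duration)
        prims.append(
            MotionPrimitive(f"{side}_hip", "rotation", j(30.0), 3, t0, w, "wavelet")
        )
    t0, w = slot(frac["torso"] * duration)
    third = w / 3.0
    prims.append(MotionPrimitive("pelvis", "bend", j(40.0), 1, t0, third))
    prims.append(MotionPrimitive("pelvis", "twist", j(40.0), 1, t0 + third, third, "wavelet"))
    prims.append(MotionPrimitive("pelvis", "side", j(20.0), 1, t0 + 2 * third, third, "wavelet"))

    # continuous pelvis sway over the whole profile
    for dof, amp in (("px", 0.03), ("py", 0.03), ("pz", 0.015)):
        prims.append(
            MotionPrimitive(
                "pelvis", dof, j(amp), max(3, int(duration / 8)), 0.0, duration,
                "wavelet", float(rng.uniform(0, 2 * np.pi)),
            )
        )
    for dof, amp in (("bend", 2.5), ("side", 2.5), ("twist", 3.0)):
        prims.append(
            MotionPrimitive(
                "pelvis", dof, j(amp), max(3, int(duration / 10)), 0.0, duration,
                "wavelet", float(rng.uniform(0, 2 * np.pi)),
            )
        )
    return MotionScript(primitives=prims, duration=duration, seed=seed)


def _build_curves(script: MotionScript) -> dict:
    curves: dict[tuple, _Curve] = {}
    for p in script.primitives:
        key = (p.joint, p.dof)
        c = curves.setdefault(key, _Curve())
        if p.kind == "pulse":
            sub = p.duration / p.reps
            for r in range(p.reps):
                c.add("pulse", p.t0 + r * sub, sub, np.deg2rad(p.amplitude))
        else:
            amp = p.amplitude if p.dof.startswith("p") else np.deg2rad(p.amplitude)
            c.add("wavelet", p.t0, p.duration, amp, p.reps, p.phase)
    return curves


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

@dataclass
class TruthTrajectory:
    """Exact per-sample trajectories of all seven IMUs plus true angles.

    ``a`` is the navigation-frame linear acceleration (second derivative of
    position, gravity not included); ``omega``/``alpha`` are the body-frame
    angular velocity and acceleration. ``segment_R`` holds the true
    anatomical orientation series; ``joint_angles`` the scripted joint DOF
    angles (radians). ``biases`` is filled by :func:`synthesize_imu`.
    """

    t: np.ndarray
    R: np.ndarray  # (N, 7, 3, 3)
    p: np.ndarray  # (N, 7, 3)
    v: np.ndarray
    a: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    segment_R: dict
    joint_angles: dict
    skeleton: SkeletonTruth
    biases: np.ndarray | None = None


def _eval(curves, key, t):
    c = curves.get(key)
    if c is None:
        z = np.zeros_like(t)
        return z, z.copy(), z.copy()
    return c.eval(t)


def _elementary(R, w, al, axis, th, thd, thdd):
    """Propagate orientation/angular kinematics through one rotating DOF."""
    Q = _bexp(np.outer(th, axis))
    QT = np.swapaxes(Q, 1, 2)
    w_loc = np.einsum("nab,nb->na", QT, w)
    wj = thd[:, None] * axis
    w_new = w_loc + wj
    al_new = (
        np.einsum("nab,nb->na", QT, al)
        - np.cross(wj, w_loc)
        + thdd[:, None] * axis
    )
    return R @ Q, w_new, al_new


def _const_link(R, w, al, Q):
    return R @ Q, w @ Q, al @ Q  # w Q == Q^T w row-wise


def _point_on(R, w, al, c_pos, c_vel, c_acc, u):
    """Kinematics of a point fixed at u (segment frame) from the origin's."""
    u = np.asarray(u, dtype=float)
    wxu = np.cross(w, u[None, :] if u.ndim == 1 else u)
    p = c_pos + np.einsum("nab,b->na", R, u)
    v = c_vel + np.einsum("nab,nb->na", R, wxu)
    acc = c_acc + np.einsum(
        "nab,nb->na", R, np.cross(al, u[None, :]) + np.cross(w, wxu)
    )
    return p, v, acc


def forward_kinematics(
    skeleton: SkeletonTruth, script: MotionScript, rate: float = 200.0
) -> TruthTrajectory:
    """Exact chain kinematics of all seven IMUs over the scripted motion."""
    if rate < 50.0:
        raise ValueError("sample rate must be at least 50 Hz")
    sk = skeleton
    dt = 1.0 / rate
    N = int(round(script.duration * rate))
    t = np.arange(N) * dt
    curves = _build_curves(script)

    joint_angles = {}

    # pelvis root
    rx, rxd, rxdd = _eval(curves, ("pelvis", "bend"), t)
    ry, ryd, rydd = _eval(curves, ("pelvis", "side"), t)
    rz, rzd, rzdd = _eval(curves, ("pelvis", "twist"), t)
    joint_angles["pelvis_bend"] = rx
    joint_angles["pelvis_side"] = ry
    joint_angles["pelvis_twist"] = rz
    R0 = np.tile(np.eye(3), (N, 1, 1))
    w0 = np.zeros((N, 3))
    a0 = np.zeros((N, 3))
    ex, ey, ez = np.eye(3)
    R0, w0, a0 = _elementary(R0, w0, a0, ex, rx, rxd, rxdd)
    R0, w0, a0 = _elementary(R0, w0, a0, ey, ry, ryd, rydd)
    R0, w0, a0 = _elementary(R0, w0, a0, ez, rz, rzd, rzdd)
    base = np.array([0.0, 0.0, sk.lumbar_height])
    px, pxd, pxdd = _eval(curves, ("pelvis", "px"), t)
    py, pyd, pydd = _eval(curves, ("pelvis", "py"), t)
    pz, pzd, pzdd = _eval(curves, ("pelvis", "pz"), t)
    p0 = base[None, :] + np.stack([px, py, pz], axis=1)
    v0 = np.stack([pxd, pyd, pzd], axis=1)
    acc0 = np.stack([pxdd, pydd, pzdd], axis=1)

    seg_R = {"pelvis": R0}
    seg_w = {"pelvis": w0}
    seg_al = {"pelvis": a0}
    seg_origin = {"pelvis": (p0, v0, acc0)}

    for side in ("right", "left"):
        hip_u = np.array(
            [sk.pelvis_width / 2.0 * (1.0 if side == "right" else -1.0), 0.0, 0.0]
        )
        hip = _point_on(R0, w0, a0, p0, v0, acc0, hip_u)

        fx, fxd, fxdd = _eval(curves, (f"{side}_hip", "flexion"), t)
        fy, fyd, fydd = _eval(curves, (f"{side}_hip", "abduction"), t)
        fz, fzd, fzdd = _eval(curves, (f"{side}_hip", "rotation"), t)
        joint_angles[f"{side}_hip_flexion"] = fx
        joint_angles[f"{side}_hip_abduction"] = fy
        joint_angles[f"{side}_hip_rotation"] = fz
        Rf, wf, alf = _elementary(R0, w0, a0, ex, fx, fxd, fxdd)
        Rf, wf, alf = _elementary(Rf, wf, alf, ey, fy, fyd, fydd)
        Rf, wf, alf = _elementary(Rf, wf, alf, ez, fz, fzd, fzdd)

        kx, kxd, kxdd = _eval(curves, (f"{side}_knee", "flexion"), t)
        joint_angles[f"{side}_knee_flexion"] = kx
        knee = _point_on(Rf, wf, alf, *hip, np.array([0.0, 0.0, -sk.femur_length]))
        Rt, wt, alt = _elementary(
            Rf, wf, alf, sk.knee_axis_femur[side], kx, kxd, kxdd
        )
        Rt, wt, alt = _const_link(Rt, wt, alt, sk.knee_neutral_rot[side])

        ax_, axd, axdd = _eval(curves, (f"{side}_ankle", "flexion"), t)
        ay_, ayd, aydd = _eval(curves, (f"{side}_ankle", "eversion"), t)
        az_, azd, azdd = _eval(curves, (f"{side}_ankle", "rotation"), t)
        joint_angles[f"{side}_ankle_flexion"] = ax_
        joint_angles[f"{side}_ankle_eversion"] = ay_
        ankle = _point_on(Rt, wt, alt, *knee, np.array([0.0, 0.0, -sk.tibia_length]))
        Rc, wc, alc = _elementary(Rt, wt, alt, ex, ax_, axd, axdd)
        Rc, wc, alc = _elementary(Rc, wc, alc, ey, ay_, ayd, aydd)
        Rc, wc, alc = _elementary(Rc, wc, alc, ez, az_, azd, azdd)

        seg_R[f"{side}_femur"] = Rf
        seg_w[f"{side}_femur"] = wf
        seg_al[f"{side}_femur"] = alf
        seg_origin[f"{side}_femur"] = hip
        seg_R[f"{side}_tibia"] = Rt
        seg_w[f"{side}_tibia"] = wt
        seg_al[f"{side}_tibia"] = alt
        seg_origin[f"{side}_tibia"] = knee
        seg_R[f"{side}_foot"] = Rc
        seg_w[f"{side}_foot"] = wc
        seg_al[f"{side}_foot"] = alc
        seg_origin[f"{side}_foot"] = ankle

    R = np.zeros((N, 7, 3, 3))
    p = np.zeros((N, 7, 3))
    v = np.zeros((N, 7, 3))
    a = np.zeros((N, 7, 3))
    omega = np.zeros((N, 7, 3))
    alpha = np.zeros((N, 7, 3))
    for imu, seg in enumerate(_IMU_SEGMENTS):
        Rm, um = sk.mounts[imu]
        Rs, ws, als = seg_R[seg], seg_w[seg], seg_al[seg]
        pi, vi, ai = _point_on(Rs, ws, als, *seg_origin[seg], um)
        R[:, imu] = Rs @ Rm
        p[:, imu] = pi
        v[:, imu] = vi
        a[:, imu] = ai
        omega[:, imu] = ws @ Rm  # == Rm^T ws row-wise
        alpha[:, imu] = als @ Rm

    segment_R = {
        k: seg_R[k]
        for k in ("pelvis", "right_femur", "right_tibia", "left_femur", "left_tibia")
    }
    return TruthTrajectory(
        t=t, R=R, p=p, v=v, a=a, omega=omega, alpha=alpha,
        segment_R=segment_R, joint_angles=joint_angles, skeleton=sk,
    )


# ---------------------------------------------------------------------------
# measurement synthesis and soft-tissue perturbation
# ---------------------------------------------------------------------------

def synthesize_imu(
    truth: TruthTrajectory,
    noise: NoiseSpec,
    seed: int = 0,
    init_bias_sigma_a: float = 0.05,
    init_bias_sigma_w: float = 0.01,
):
    """Corrupt the exact trajectories into gyro/accel streams.

    gyro = omega + b_w + white noise; accel = R^T (a - g) + b_a + white
    noise, with per-sample white-noise variance density^2/dt and biases
    evolving as seeded random walks from small random initial values. The
    true bias series is stored back on the returned truth copy.

    Returns ``(streams, truth_with_biases)``.
    """
    rng = np.random.default_rng(seed)
    N = len(truth.t)
    dt = noise.dt
    sd_w = noise.sigma_w / np.sqrt(dt)
    sd_a = noise.sigma_a / np.sqrt(dt)

    biases = np.zeros((N, 7, 6))
    b0 = np.concatenate(
        [
            rng.normal(0.0, init_bias_sigma_a, size=(7, 3)),
            rng.normal(0.0, init_bias_sigma_w, size=(7, 3)),
        ],
        axis=1,
    )
    walk_sd = np.concatenate(
        [
            np.full(3, noise.sigma_ba_walk * np.sqrt(dt)),
            np.full(3, noise.sigma_bw_walk * np.sqrt(dt)),
        ]
    )
    steps = rng.normal(size=(N, 7, 6)) * walk_sd
    biases = b0[None] + np.concatenate(
        [np.zeros((1, 7, 6)), np.cumsum(steps[:-1], axis=0)], axis=0
    )

    g = noise.gravity
    specific = np.einsum("nsba,nsb->nsa", truth.R, truth.a - g[None, None, :])
    gyro = (
        truth.omega
        + biases[:, :, 3:]
        + rng.normal(size=(N, 7, 3)) * sd_w
    )
    accel = (
        specific
        + biases[:, :, :3]
        + rng.normal(size=(N, 7, 3)) * sd_a
    )
    streams = [ImuStream(truth.t.copy(), gyro[:, s], accel[:, s]) for s in range(7)]
    truth_out = replace(truth, biases=biases)
    return streams, truth_out


def calibrate_covariances(truth: TruthTrajectory, noise: NoiseSpec) -> NoiseSpec:
    """Set the hinge/joint/angular-velocity factor covariances from the
    empirical residual distributions at ground truth.

    Mirrors the calibration a practitioner performs against a reference
    measurement system: the hinge and joint-center residuals are evaluated
    at the true states and statics over all keyframes, their zero-mean
    Gaussian covariances fitted, isotropized (trace/3, which preserves the
    exact heading-gauge invariance of the total error), and floored by the
    analytic contribution of the discrete gyroscope noise. The
    angular-velocity covariance is the known discrete white-noise variance.
    Returns a copy of ``noise`` with the three covariances replaced.
    """
    from dataclasses import replace as _dc_replace

    from .factors import fit_noise_covariance, hinge_residual, joint_center_residual
    from .graph import HINGE_SPECS, JOINT_SPECS
    from .manifold import Pose

    d = noise.decimation
    N = len(truth.t)
    kf = np.arange((N - 1) // d + 1) * d
    var_g = noise.sigma_w ** 2 / noise.dt

    sk = truth.skeleton
    hinge_samples = []
    for axis, A, B in HINGE_SPECS:
        r = sk.axes[axis]
        for k in kf:
            hinge_samples.append(
                hinge_residual(
                    r, truth.R[k, A], truth.R[k, B],
                    truth.omega[k, A], truth.omega[k, B],
                )
            )
    joint_samples = []
    for _, A, sA, B, sB in JOINT_SPECS:
        for k in kf:
            joint_samples.append(
                joint_center_residual(
                    Pose(truth.R[k, A], truth.p[k, A]), sk.offsets[sA],
                    Pose(truth.R[k, B], truth.p[k, B]), sk.offsets[sB],
                )
            )
    var_hinge = float(np.trace(fit_noise_covariance(hinge_samples)) / 3.0)
    var_joint = float(np.trace(fit_noise_covariance(joint_samples)) / 3.0)
    return _dc_replace(
        noise,
        cov_angvel=(var_g + 1e-8) * np.eye(3),
        cov_hinge=(var_hinge + 2.0 * var_g + 1e-8) * np.eye(3),
        cov_joint=(var_joint + 1e-6) * np.eye(3),
    )


def truth_values(truth: TruthTrajectory, noise: NoiseSpec, anchored: bool = True):
    """Ground-truth keyframe variable assignment for a synthetic trajectory.

    Subsamples the exact per-sample truth at the keyframe rate and fills a
    :class:`~kinegraph.graph.Values` with true poses, velocities, angular
    velocities, biases (zero when measurements were never synthesized), and
    the true skeleton statics. With ``anchored`` the assignment is moved
    into the anchored gauge (first lumbar state at zero position, velocity,
    and heading), which leaves every factor residual unchanged.
    """
    from .graph import Values, apply_gauge

    d = noise.decimation
    N = len(truth.t)
    M = (N - 1) // d + 1
    kf = np.arange(M) * d
    vals = Values.zeros(M)
    vals.R = truth.R[kf].copy()
    vals.p = truth.p[kf].copy()
    vals.v = truth.v[kf].copy()
    vals.w = truth.omega[kf].copy()
    if truth.biases is not None:
        vals.b = truth.biases[kf].copy()
    sk = truth.skeleton
    from .graph import _AXIS_INDEX, _OFFSET_INDEX

    for name, i in _AXIS_INDEX.items():
        vals.axes[i] = np.asarray(sk.axes[name], dtype=float)
    for name, i in _OFFSET_INDEX.items():
        vals.offsets[i] = np.asarray(sk.offsets[name], dtype=float)
    if anchored:
        R00 = vals.R[0, 0]
        vals = apply_gauge(
            vals, truth.t[kf], dyaw=-float(np.arctan2(R00[1, 0], R00[0, 0]))
        )
        vals = apply_gauge(
            vals, truth.t[kf], dp=-vals.p[0, 0].copy(), dv=-vals.v[0, 0].copy()
        )
    return vals


def perturb_soft_tissue(
    truth: TruthTrajectory,
    amp_pos_mm: float = 5.0,
    amp_rot_deg: float = 1.0,
    frequency: float = 1.0,
    seed: int = 0,
) -> TruthTrajectory:
    """Superimpose oscillatory soft-tissue motion on each IMU mounting pose.

    Each IMU (except the sacral one, which sits over bone) is displaced in
    its own frame by independent sinusoids of amplitude ``amp_pos_mm`` and
    rotated about a fixed random axis by a sinusoid of ``amp_rot_deg``, with
    per-axis frequency jitter around ``frequency`` so the components
    decorrelate. Zero amplitude returns the input unchanged. Because the
    perturbations are zero-mean sinusoids, the induced joint-center
    residuals average out over the trajectory while their instantaneous
    norm is bounded by the construction amplitudes.
    """
    if amp_pos_mm == 0.0 and amp_rot_deg == 0.0:
        return truth
    rng = np.random.default_rng(seed)
    N = len(truth.t)
    t = truth.t
    amp = amp_pos_mm * 1e-3
    eta0 = np.deg2rad(amp_rot_deg)

    R = truth.R.copy()
    p = truth.p.copy()
    v = truth.v.copy()
    a = truth.a.copy()
    omega = truth.omega.copy()
    alpha = truth.alpha.copy()

    for imu in range(1, 7):
        # translation d(t) in the IMU frame
        f3 = frequency * rng.uniform(0.8, 1.2, size=3)
        ph3 = rng.uniform(0, 2 * np.pi, size=3)
        om3 = 2 * np.pi * f3
        arg = np.outer(t, om3) + ph3
        d = amp * np.sin(arg)
        dd = amp * om3 * np.cos(arg)
        ddd = -amp * om3 ** 2 * np.sin(arg)
        # rotation eta(t) about a fixed axis in the IMU frame
        ax_r = rng.normal(size=3)
        ax_r /= np.linalg.norm(ax_r)
        fr = frequency * rng.uniform(0.8, 1.2)
        phr = rng.uniform(0, 2 * np.pi)
        omr = 2 * np.pi * fr
        eta = eta0 * np.sin(omr * t + phr)
        etad = eta0 * omr * np.cos(omr * t + phr)
        etadd = -eta0 * omr ** 2 * np.sin(omr * t + phr)

        Ri = truth.R[:, imu]
        wi = truth.omega[:, imu]
        ali = truth.alpha[:, imu]
        Q = _bexp(np.outer(eta, ax_r))
        R[:, imu] = Ri @ Q
        w_loc = np.einsum("nab,nb->na", np.swapaxes(Q, 1, 2), wi)
        wj = etad[:, None] * ax_r
        omega[:, imu] = w_loc + wj
        alpha[:, imu] = (
            np.einsum("nab,nb->na", np.swapaxes(Q, 1, 2), ali)
            - np.cross(wj, w_loc)
            + etadd[:, None] * ax_r
        )
        wxd = np.cross(wi, d)
        p[:, imu] = truth.p[:, imu] + np.einsum("nab,nb->na", Ri, d)
        v[:, imu] = truth.v[:, imu] + np.einsum("nab,nb->na", Ri, wxd + dd)
        a[:, imu] = truth.a[:, imu] + np.einsum(
            "nab,nb->na",
            Ri,
            np.cross(ali, d) + np.cross(wi, wxd) + 2.0 * np.cross(wi, dd) + ddd,
        )
    return replace(truth, R=R, p=p, v=v, a=a, omega=omega, alpha=alpha)
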