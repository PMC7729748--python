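"""Anatomical post-processing: axis disambiguation, segment frames,
joint-coordinate-system knee angles, and evaluation metrics.

Anatomical segment axes follow the ISB convention: z positive proximal,
y positive anterior, x positive to the subject's right. The knee's three
rotation angles are reported in the Grood-Suntay joint coordinate system:
flexion about the femoral x axis (flexion negative, so the knee's range of
motion lies roughly in [+10 deg, -150 deg]), internal/external rotation
about the tibial z axis, and ab/adduction from the angle between those two
body-fixed axes, with signs mirrored between sides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import HINGE_SPECS, Solution
from .manifold import rot_exp

__all__ = [
    "KneeAngleSeries",
    "SegmentFrames",
    "disambiguate_axes",
    "build_lcs",
    "segment_orientation",
    "knee_angles",
    "solution_knee_angles",
    "solution_segment_rotations",
    "distance_rmse",
    "angle_error_stats",
    "pitch_roll",
    "pitch_roll_rmse",
]

# per side: (axis names (proximal thigh frame, distal shank frame),
#            thigh IMU, shank IMU, thigh offsets (prox, dist), shank offsets)
_SIDE_CONFIG = {
    "right": ("r2", "r3", 1, 2, ("s2rh", "s2rk"), ("s3rk", "s3ra")),
    "left": ("r5", "r6", 4, 5, ("s5lh", "s5lk"), ("s6lk", "s6la")),
}


@dataclass
class KneeAngleSeries:
    """Per-keyframe knee angles in degrees for one side."""

    side: str
    flexion: np.ndarray
    rotation: np.ndarray
    adduction: np.ndarray
    gimbal_flag: bool = False

    def __len__(self) -> int:
        return len(self.flexion)


@dataclass
class SegmentFrames:
    """Anatomical orientation series R^N_seg plus the static IMU-to-segment
    rotation for one segment."""

    name: str
    R_imu_to_seg: np.ndarray  # rows are the anatomical axes in the IMU frame
    R_seg_N: np.ndarray  # (M, 3, 3)


def build_lcs(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Orthonormal leg coordinate system from a right axis and proximal axis.

    Returns the rotation whose rows are (x projected orthogonal to z,
    z cross x, z), each normalized; the proximal direction is kept exactly
    and the right direction corrected for orthogonality. Inputs need not be
    unit or orthogonal, only nonzero and nonparallel.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    zx = np.cross(z, x)
    nzx = np.linalg.norm(zx)
    if nzx < 1e-12 or np.linalg.norm(x) < 1e-12 or np.linalg.norm(z) < 1e-12:
        raise ValueError("axis and proximal vector must be nonzero and nonparallel")
    row_x = np.cross(zx, z)
    R = np.vstack(
        [
            row_x / np.linalg.norm(row_x),
            zx / nzx,
            z / np.linalg.norm(z),
        ]
    )
    return R


def segment_orientation(r: np.ndarray, s_prox: np.ndarray, s_dist: np.ndarray) -> np.ndarray:
    """Static IMU-to-anatomical rotation from the knee axis and the
    IMU-frame proximal vector ``s_prox - s_dist``.

    The rows of the result are the anatomical axes expressed in the IMU
    frame; composing with the IMU trajectory as ``R^N_seg = R^N_imu @ R.T``
    gives the anatomical orientation series.
    """
    d = np.asarray(s_prox, dtype=float) - np.asarray(s_dist, dtype=float)
    return build_lcs(r, d / np.linalg.norm(d))


def knee_angles(R_femur_N, R_tibia_N, side: str) -> KneeAngleSeries:
    """Grood-Suntay decomposition of the femur/tibia relative orientation.

    Body-fixed axes: e1 = femoral x (to the right), e3 = tibial z
    (proximal); floating axis e2 = e3 x e1 normalized. Flexion is the
    rotation about e1 (negative in flexion), internal/external rotation is
    about e3, and ab/adduction comes from the angle between e1 and e3 with
    the sign mirrored between sides. Only the relative orientation enters,
    so the output is invariant to any common navigation-frame rotation.
    """
    Rf = np.asarray(R_femur_N, dtype=float)
    Rt = np.asarray(R_tibia_N, dtype=float)
    if Rf.shape != Rt.shape:
        raise ValueError("femur and tibia orientation sequences differ in length")
    if Rf.ndim == 2:
        Rf = Rf[None]
        Rt = Rt[None]
    # everything is computed in the femur frame: rel maps tibia coords there
    rel = np.swapaxes(Rf, 1, 2) @ Rt
    e1 = np.broadcast_to(np.array([1.0, 0.0, 0.0]), (len(rel), 3))
    e3 = rel[:, :, 2]  # tibial z in femur frame
    c13 = np.clip(np.sum(e1 * e3, axis=1), -1.0, 1.0)
    gimbal = bool(np.any(np.abs(c13) > 0.999))
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2, axis=1, keepdims=True)
    e2 = e2 / np.where(n2 > 1e-12, n2, 1.0)
    # flexion: angle of e2 from the femoral y axis, about e1
    flexion = np.arctan2(e2[:, 2], e2[:, 1])
    # internal/external rotation: angle of e2 from the tibial y axis, about e3
    Xt = rel[:, :, 0]
    Yt = rel[:, :, 1]
    rotation = np.arctan2(np.sum(e2 * Xt, axis=1), np.sum(e2 * Yt, axis=1))
    beta = np.arccos(c13)
    adduction = beta - 0.5 * np.pi
    if side == "left":
        rotation = -rotation
        adduction = -adduction
    elif side != "right":
        raise ValueError("side must be 'left' or 'right'")
    return KneeAngleSeries(
        side=side,
        flexion=np.rad2deg(flexion),
        rotation=np.rad2deg(rotation),
        adduction=np.rad2deg(adduction),
        gimbal_flag=gimbal,
    )


def _knee_axes_nav(values, axis_prox, axis_dist, imu_A, imu_B):
    aA = np.einsum("kab,b->ka", values.R[:, imu_A], values.axis(axis_prox))
    aB = np.einsum("kab,b->ka", values.R[:, imu_B], values.axis(axis_dist))
    return aA, aB


def _side_flexion(values, side: str) -> np.ndarray:
    ax_p, ax_d, iA, iB, th_off, sh_off = _SIDE_CONFIG[side]
    R_f_imu = segment_orientation(
        values.axis(ax_p), values.offset(th_off[0]), values.offset(th_off[1])
    )
    R_t_imu = segment_orientation(
        values.axis(ax_d), values.offset(sh_off[0]), values.offset(sh_off[1])
    )
    Rf = values.R[:, iA] @ R_f_imu.T[None]
    Rt = values.R[:, iB] @ R_t_imu.T[None]
    return knee_angles(Rf, Rt, side).flexion


def disambiguate_axes(solution: Solution) -> Solution:
    """Resolve the four-fold knee-axis sign ambiguity so both axes of each
    knee point to the subject's right.

    Step 1 aligns the distal axis with the proximal one: both are rotated
    into the navigation frame at every keyframe and the distal axis is
    flipped when the median inter-axis angle exceeds 90 degrees. Step 2
    fixes the common side: if the median knee flexion computed after step 1
    exceeds +20 degrees, both axes must have pointed left, and both are
    flipped. Idempotent; the four sign combinations all map to the same
    output.
    """
    values = solution.values.copy()
    for side in ("right", "left"):
        ax_p, ax_d, iA, iB, *_ = _SIDE_CONFIG[side]
        from .graph import _AXIS_INDEX  # fixed axis ordering

        aA, aB = _knee_axes_nav(values, ax_p, ax_d, iA, iB)
        cosang = np.clip(np.sum(aA * aB, axis=1), -1.0, 1.0)
        med = float(np.median(np.degrees(np.arccos(cosang))))
        if abs(med - 90.0) < 1e-6 * 90.0:
            raise ValueError(
                f"{side} knee axes are exactly orthogonal on median; "
                "sign disambiguation is genuinely ambiguous"
            )
        if med > 90.0:
            values.axes[_AXIS_INDEX[ax_d]] = -values.axes[_AXIS_INDEX[ax_d]]
        flexion = _side_flexion(values, side)
        if float(np.median(flexion)) > 20.0:
            values.axes[_AXIS_INDEX[ax_p]] = -values.axes[_AXIS_INDEX[ax_p]]
            values.axes[_AXIS_INDEX[ax_d]] = -values.axes[_AXIS_INDEX[ax_d]]
    return replace(solution, values=values, skeleton=values.skeleton())


def solution_segment_rotations(solution: Solution) -> dict:
    """Anatomical femur/tibia orientation series derived from a solution."""
    values = solution.values
    out = {}
    for side in ("right", "left"):
        ax_p, ax_d, iA, iB, th_off, sh_off = _SIDE_CONFIG[side]
        R_f_imu = segment_orientation(
            values.axis(ax_p), values.offset(th_off[0]), values.offset(th_off[1])
        )
        R_t_imu = segment_orientation(
            values.axis(ax_d), values.offset(sh_off[0]), values.offset(sh_off[1])
        )
        out[f"{side}_femur"] = SegmentFrames(
            f"{side}_femur", R_f_imu, values.R[:, iA] @ R_f_imu.T[None]
        )
        out[f"{side}_tibia"] = SegmentFrames(
            f"{side}_tibia", R_t_imu, values.R[:, iB] @ R_t_imu.T[None]
        )
    return out


def solution_knee_angles(solution: Solution) -> dict:
    """Knee angle series for both sides from a (disambiguated) solution."""
    frames = solution_segment_rotations(solution)
    return {
        side: knee_angles(
            frames[f"{side}_femur"].R_seg_N, frames[f"{side}_tibia"].R_seg_N, side
        )
        for side in ("right", "left")
    }


def distance_rmse(est_positions, ref_positions) -> float:
    """RMSE (in centimetres) of the inter-IMU separation distance.

    ``est_positions`` and ``ref_positions`` are each a pair of (M, 3)
    navigation-frame position sequences in metres; the statistic compares
    the scalar separation ``|p_A - p_B|`` between the two sources, which is
    invariant to the unobservable global pose offset.
    """
    eA, eB = (np.asarray(a, dtype=float) for a in est_positions)
    rA, rB = (np.asarray(a, dtype=float) for a in ref_positions)
    if not (len(eA) == len(eB) == len(rA) == len(rB)):
        raise ValueError("position sequences differ in length")
    d_est = np.linalg.norm(eA - eB, axis=1)
    d_ref = np.linalg.norm(rA - rB, axis=1)
    return float(np.sqrt(np.mean((d_est - d_ref) ** 2))) * 100.0


def angle_error_stats(est, ref):
    """RMSE and peak absolute error (degrees) between two angle series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("angle sequences differ in length")
    d = est - ref
    return float(np.sqrt(np.mean(d * d))), float(np.max(np.abs(d)))


def pitch_roll(R) -> tuple:
    """Pitch and roll (rad) of orientation(s) under a Z-Y-X Euler convention.

    These are the gravity-referenced degrees of freedom, well defined even
    though the heading (yaw) is only known up to the gauge.
    """
    R = np.asarray(R, dtype=float)
    pitch = -np.arcsin(np.clip(R[..., 2, 0], -1.0, 1.0))
    roll = np.arctan2(R[..., 2, 1], R[..., 2, 2])
    return pitch, roll


def pitch_roll_rmse(R_est, R_ref):
    """RMSE (degrees) of pitch and roll between two orientation sequences."""
    pe, re_ = pitch_roll(R_est)
    pr, rr = pitch_roll(R_ref)
    dp = np.rad2deg(pe - pr)
    dr = np.rad2deg(np.arctan2(np.sin(re_ - rr), np.cos(re_ - rr)))
    return float(np.sqrt(np.mean(dp ** 2))), float(np.sqrt(np.mean(dr ** 2)))
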