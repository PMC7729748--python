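"""File formats, configuration, and serialization.

All on-disk formats are plain text: long-format CSV for IMU measurement
tables and keyframe states, JSON for skeleton variables and truth sidecars,
line-oriented text for the solver log, flat YAML for configuration. Units
in files are SI (s, rad/s, m/s^2, m); angles files are in degrees.
Orientations are serialized as unit quaternions (w, x, y, z) to avoid
matrix row-order ambiguity. Floats are written with 17 significant digits
so write -> read -> write round-trips are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation as ScipyRotation

from .graph import N_IMUS, Solution, SolverConfig, Values
from .imu import ImuStream, NoiseSpec

__all__ = [
    "read_imu_table",
    "write_imu_table",
    "write_solution",
    "read_solution",
    "write_knee_angles",
    "read_knee_angles",
    "load_config",
    "default_config",
    "noise_from_config",
    "solver_from_config",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
_IMU_COLUMNS = ["t", "imu_id", "gx", "gy", "gz", "ax", "ay", "az"]


def read_imu_table(path) -> list:
    """Read a long-format IMU measurement table into 7 per-IMU streams.

    The CSV must contain columns t, imu_id (1-7), gx, gy, gz (rad/s), and
    ax, ay, az (m/s^2). Rows are sorted by time per IMU; all seven IMUs
    must be present with strictly increasing, uniform timestamps.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    present = sorted(df["imu_id"].unique())
    expected = list(range(1, N_IMUS + 1))
    if present != expected:
        absent = sorted(set(expected) - set(present))
        raise ValueError(
            f"missing imu_id {absent}; present ids: {present}"
        )
    streams = []
    for imu_id in expected:
        sub = df[df["imu_id"] == imu_id].sort_values("t", kind="stable")
        t = sub["t"].to_numpy()
        dts = np.diff(t)
        if np.any(dts <= 0):
            line = int(sub.index[1:][dts <= 0][0]) + 2  # header + 1-based
            raise ValueError(f"non-monotone time for imu {imu_id} at line {line}")
        if len(dts) > 1 and np.any(np.abs(dts - dts[0]) > 1e-6):
            line = int(sub.index[1:][np.abs(dts - dts[0]) > 1e-6][0]) + 2
            raise ValueError(f"non-uniform timing for imu {imu_id} at line {line}")
        streams.append(
            ImuStream(t, sub[["gx", "gy", "gz"]].to_numpy(), sub[["ax", "ay", "az"]].to_numpy())
        )
    logger.info(
        "read %d samples per IMU spanning %.3f s", len(streams[0]),
        streams[0].t[-1] - streams[0].t[0],
    )
    return streams


def write_imu_table(streams, path) -> None:
    """Write 7 per-IMU streams as one long-format CSV (bit-exact floats)."""
    frames = []
    for i, s in enumerate(streams, start=1):
        frames.append(
            pd.DataFrame(
                {
                    "t": s.t,
                    "imu_id": i,
                    "gx": s.gyro[:, 0], "gy": s.gyro[:, 1], "gz": s.gyro[:, 2],
                    "ax": s.accel[:, 0], "ay": s.accel[:, 1], "az": s.accel[:, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _quat_wxyz(R: np.ndarray) -> np.ndarray:
    q = ScipyRotation.from_matrix(R).as_quat()  # x, y, z, w
    q = np.roll(q, 1, axis=-1)  # w, x, y, z
    # canonical sign: w >= 0
    flip = q[..., 0] < 0
    q[flip] = -q[flip]
    return q


def _matrix_from_wxyz(q: np.ndarray) -> np.ndarray:
    return ScipyRotation.from_quat(np.roll(q, -1, axis=-1)).as_matrix()


def write_solution(solution: Solution, angles, out_dir) -> None:
    """Write solver output: keyframe states (CSV), skeleton variables
    (JSON), knee angles (CSV), and the iteration log (text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vals = solution.values
    M = vals.M
    times = (
        solution.keyframe_times
        if solution.keyframe_times is not None
        else np.arange(M, dtype=float)
    )
    cached = solution.quaternions
    if cached is not None and not np.array_equal(
        _matrix_from_wxyz(cached.reshape(-1, 4)).reshape(vals.R.shape), vals.R
    ):
        cached = None  # orientations were modified since reading
    rows = []
    for s in range(N_IMUS):
        q = cached[:, s] if cached is not None else _quat_wxyz(vals.R[:, s])
        rows.append(
            pd.DataFrame(
                {
                    "t": times, "imu_id": s + 1,
                    "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3],
                    "px": vals.p[:, s, 0], "py": vals.p[:, s, 1], "pz": vals.p[:, s, 2],
                    "vx": vals.v[:, s, 0], "vy": vals.v[:, s, 1], "vz": vals.v[:, s, 2],
                    "wx": vals.w[:, s, 0], "wy": vals.w[:, s, 1], "wz": vals.w[:, s, 2],
                    "bax": vals.b[:, s, 0], "bay": vals.b[:, s, 1], "baz": vals.b[:, s, 2],
                    "bwx": vals.b[:, s, 3], "bwy": vals.b[:, s, 4], "bwz": vals.b[:, s, 5],
                }
            )
        )
    pd.concat(rows).to_csv(out / "states.csv", index=False, float_format=_FLOAT_FMT)

    skel = solution.skeleton
    with open(out / "skeleton.json", "w") as fh:
        json.dump(
            {
                "axes": {k: [repr(float(x)) for x in v] for k, v in skel.axes.items()},
                "offsets": {k: [repr(float(x)) for x in v] for k, v in skel.offsets.items()},
                "final_error": repr(float(solution.final_error)),
                "iterations": solution.iterations,
                "termination": solution.termination,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    if angles is not None:
        write_knee_angles(angles, times, out / "angles.csv")
    with open(out / "solver_log.txt", "w") as fh:
        fh.write("\n".join(solution.log) + ("\n" if solution.log else ""))


def write_knee_angles(angles: dict, times, path) -> None:
    rows = []
    for side, series in angles.items():
        rows.append(
            pd.DataFrame(
                {
                    "t": times, "side": side,
                    "flexion": series.flexion,
                    "rotation": series.rotation,
                    "adduction": series.adduction,
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_knee_angles(path) -> dict:
    from .anatomy import KneeAngleSeries

    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for side in df["side"].unique():
        sub = df[df["side"] == side]
        out[str(side)] = KneeAngleSeries(
            side=str(side),
            flexion=sub["flexion"].to_numpy(),
            rotation=sub["rotation"].to_numpy(),
            adduction=sub["adduction"].to_numpy(),
        )
    return out


def read_solution(out_dir) -> Solution:
    """Read solver output written by :func:`write_solution`."""
    out = Path(out_dir)
    df = pd.read_csv(out / "states.csv", float_precision="round_trip")
    M = (df["imu_id"] == 1).sum()
    vals = Values.zeros(M)
    quats = np.zeros((M, N_IMUS, 4))
    times = df[df["imu_id"] == 1]["t"].to_numpy()
    for s in range(N_IMUS):
        sub = df[df["imu_id"] == s + 1]
        q = sub[["qw", "qx", "qy", "qz"]].to_numpy()
        quats[:, s] = q
        vals.R[:, s] = _matrix_from_wxyz(q)
        vals.p[:, s] = sub[["px", "py", "pz"]].to_numpy()
        vals.v[:, s] = sub[["vx", "vy", "vz"]].to_numpy()
        vals.w[:, s] = sub[["wx", "wy", "wz"]].to_numpy()
        vals.b[:, s] = sub[["bax", "bay", "baz", "bwx", "bwy", "bwz"]].to_numpy()
    with open(out / "skeleton.json") as fh:
        sk = json.load(fh)
    from .graph import _AXIS_INDEX, _OFFSET_INDEX

    for k, i in _AXIS_INDEX.items():
        vals.axes[i] = np.array([float(x) for x in sk["axes"][k]])
    for k, i in _OFFSET_INDEX.items():
        vals.offsets[i] = np.array([float(x) for x in sk["offsets"][k]])
    log_path = out / "solver_log.txt"
    log = log_path.read_text().splitlines() if log_path.exists() else []
    return Solution(
        values=vals,
        skeleton=vals.skeleton(),
        final_error=float(sk["final_error"]),
        iterations=int(sk["iterations"]),
        termination=sk["termination"],
        log=log,
        keyframe_times=times,
        quaternions=quats,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Flat key-value configuration with shipped defaults."""
    return {
        "rate": 200.0,
        "decimation": 20,
        "sigma_w": 0.005,
        "sigma_a": 0.05,
        "sigma_bw_walk": 1e-4,
        "sigma_ba_walk": 1e-4,
        "sigma_angvel": 0.005,
        "sigma_hinge": 0.05,
        "sigma_joint": 0.01,
        "gravity_z": -9.81,
        "window_sigma": 0.01,
        "abs_error_tol": 1e-6,
        "rel_error_tol": 1e-4,
        "max_iterations": 10000,
        "lm_lambda_init": 1e-5,
        "duration": 60.0,
        "soft_tissue_mm": 5.0,
        "soft_tissue_deg": 1.0,
        "soft_tissue_hz": 1.0,
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def noise_from_config(cfg: dict) -> NoiseSpec:
    return NoiseSpec(
        sigma_w=float(cfg["sigma_w"]),
        sigma_a=float(cfg["sigma_a"]),
        sigma_bw_walk=float(cfg["sigma_bw_walk"]),
        sigma_ba_walk=float(cfg["sigma_ba_walk"]),
        cov_angvel=float(cfg["sigma_angvel"]) ** 2 * np.eye(3),
        cov_hinge=float(cfg["sigma_hinge"]) ** 2 * np.eye(3),
        cov_joint=float(cfg["sigma_joint"]) ** 2 * np.eye(3),
        gravity=np.array([0.0, 0.0, float(cfg["gravity_z"])]),
        dt=1.0 / float(cfg["rate"]),
        decimation=int(cfg["decimation"]),
    )


def solver_from_config(cfg: dict, seed: int = 0) -> SolverConfig:
    return SolverConfig(
        abs_error_tol=float(cfg["abs_error_tol"]),
        rel_error_tol=float(cfg["rel_error_tol"]),
        max_iterations=int(cfg["max_iterations"]),
        lm_lambda_init=float(cfg["lm_lambda_init"]),
        seed=seed,
    )
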