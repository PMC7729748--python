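"""Biomechanical and anthropometric residual models.

These are the constraints that tie the seven IMU trajectories to a single
underlying skeleton:

* knee hinge: the relative angular velocity across a (pseudo-)hinge joint is
  parallel to the static hinge axis expressed in a flanking IMU frame;
* joint centers: a static offset vector in each flanking IMU frame maps,
  through the IMU poses, to the same navigation-frame point;
* axis-segment angle: the angle between the knee axis and the femur/tibia
  proximal direction follows a population distribution (it is not exactly
  90 degrees), which also pins the knee center along the medial/lateral line;
* segment length, hard length windows, and left/right length discrepancy
  from population anthropometry.

Every residual is zero-mean Gaussian by construction; covariances/standard
deviations live with the factor, not here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .manifold import Pose, pose_act

__all__ = [
    "SkeletonVars",
    "AxisSegmentPrior",
    "AnthroPrior",
    "relative_angvel",
    "hinge_residual",
    "joint_center_residual",
    "axis_segment_angle_residual",
    "segment_length_residual",
    "length_window_penalty",
    "length_window_derivative",
    "discrepancy_residual",
    "compose_population_prior",
    "fit_noise_covariance",
    "load_anthropometry",
    "OFFSET_NAMES",
    "AXIS_NAMES",
]

logger = logging.getLogger(__name__)

# static-variable naming used across the package: axes by IMU id, offsets by
# IMU id + joint tag (rh/lh = right/left hip, rk/lk = knee, ra/la = ankle)
AXIS_NAMES = ("r2", "r3", "r5", "r6")
OFFSET_NAMES = (
    "s1rh", "s1lh",
    "s2rh", "s2rk",
    "s3rk", "s3ra",
    "s4ra",
    "s5lh", "s5lk",
    "s6lk", "s6la",
    "s7la",
)


@dataclass
class SkeletonVars:
    """Static calibration variables: knee axes and IMU-to-joint offsets.

    ``axes`` maps axis names (r2, r3, r5, r6) to unit 3-vectors in the
    owning IMU's frame; ``offsets`` maps offset names to 3-vectors in metres.
    """

    axes: dict
    offsets: dict

    def __post_init__(self) -> None:
        self.axes = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        self.offsets = {k: np.asarray(v, dtype=float) for k, v in self.offsets.items()}

    def validate(self) -> None:
        for k in AXIS_NAMES:
            n = np.linalg.norm(self.axes[k])
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"axis {k} is not unit norm ({n})")
        for k in OFFSET_NAMES:
            if np.linalg.norm(self.offsets[k]) >= 2.0:
                raise ValueError(f"offset {k} exceeds 2 m")

    @classmethod
    def nominal(cls) -> "SkeletonVars":
        """Nominal alignment used to initialize the optimizer.

        Knee axes point along IMU +x; thigh/shank offsets point 0.2 m along
        IMU z toward the proximal/distal joint; the lumbar IMU sees the hips
        0.09 m laterally and 0.10 m below; foot IMUs see the ankle 0.1 m up.
        """
        axes = {k: np.array([1.0, 0.0, 0.0]) for k in AXIS_NAMES}
        up = np.array([0.0, 0.0, 0.2])
        offsets = {
            "s1rh": np.array([0.09, 0.0, -0.1]),
            "s1lh": np.array([-0.09, 0.0, -0.1]),
            "s2rh": up.copy(), "s2rk": -up,
            "s3rk": up.copy(), "s3ra": -up,
            "s4ra": np.array([0.0, 0.0, 0.1]),
            "s5lh": up.copy(), "s5lk": -up,
            "s6lk": up.copy(), "s6la": -up,
            "s7la": np.array([0.0, 0.0, 0.1]),
        }
        return cls(axes=axes, offsets=offsets)


@dataclass
class AxisSegmentPrior:
    """Expected angle (rad) between a knee axis and a segment's proximal vector."""

    mu: float
    sigma: float
    segment: str

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < np.pi):
            raise ValueError("axis-segment mean angle must lie in (0, pi)")
        if self.sigma <= 0:
            raise ValueError("axis-segment sigma must be positive")


@dataclass
class AnthroPrior:
    """Population prior on the distance between two joint centers (metres)."""

    mu_L: float
    sigma_L: float
    L_min: float
    L_max: float
    a: float = 100.0
    sigma_D: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.L_min < self.L_max):
            raise ValueError("length window must satisfy 0 <= L_min < L_max")
        if self.sigma_L <= 0 or self.a <= 0:
            raise ValueError("sigma_L and window sharpness must be positive")


def relative_angvel(R_A, R_B, omega_A, omega_B) -> np.ndarray:
    """Relative angular velocity across a joint, expressed in frame A."""
    return R_A.T @ (R_B @ np.asarray(omega_B, dtype=float)) - np.asarray(
        omega_A, dtype=float
    )


def hinge_residual(r, R_A, R_B, omega_A, omega_B) -> np.ndarray:
    """Rejection of the relative angular velocity from the hinge axis.

    Zero iff the relative angular velocity is parallel to ``r``; invariant
    under ``r -> -r`` (the axis sign is structurally unidentifiable and
    resolved post hoc). Swapping the A/B arguments gives the distal-frame
    form of the same constraint.
    """
    r = np.asarray(r, dtype=float)
    m = relative_angvel(R_A, R_B, omega_A, omega_B)
    return m - (m @ r) * r


def joint_center_residual(X_A: Pose, s_A, X_B: Pose, s_B) -> np.ndarray:
    """Mismatch of the two IMU-frame joint-center offsets in the navigation frame."""
    return pose_act(X_A, s_A) - pose_act(X_B, s_B)


def axis_segment_angle_residual(
    r, s_prox, s_dist, prior: AxisSegmentPrior
) -> float:
    """Deviation of the axis-to-segment angle from its population mean (rad)."""
    r = np.asarray(r, dtype=float)
    d = np.asarray(s_prox, dtype=float) - np.asarray(s_dist, dtype=float)
    n = np.linalg.norm(d)
    if n == 0.0:
        raise ValueError("zero-length segment: proximal and distal offsets coincide")
    c = float(r @ d) / n
    if abs(c) > 1.0:
        if abs(c) > 1.0 + 1e-9:
            logger.warning("arccos argument %.17g clamped to [-1, 1]", c)
        c = float(np.clip(c, -1.0, 1.0))
    return prior.mu - float(np.arccos(c))


def segment_length_residual(s_j1, s_j2, prior: AnthroPrior) -> float:
    """Deviation of the inter-joint distance from the population mean length."""
    return float(
        np.linalg.norm(np.asarray(s_j1, dtype=float) - np.asarray(s_j2, dtype=float))
        - prior.mu_L
    )


def length_window_penalty(x: float, prior: AnthroPrior) -> float:
    """Smooth one-sided penalty outside the hard anthropometric window.

    Zero on [L_min, L_max]; grows as ``(x - L_max) tanh^2(a (x - L_max))``
    above the window (mirrored below), which is continuously differentiable
    at the joins and asymptotically linear. ``a`` tunes the constraint's
    stiffness near the boundary.
    """
    if x > prior.L_max:
        y = prior.a * (x - prior.L_max)
        return (x - prior.L_max) * np.tanh(y) ** 2
    if x < prior.L_min:
        y = prior.a * (prior.L_min - x)
        return (prior.L_min - x) * np.tanh(y) ** 2
    return 0.0


def length_window_derivative(x: float, prior: AnthroPrior) -> float:
    """d/dx of :func:`length_window_penalty` (zero inside the window)."""
    if x > prior.L_max:
        u = x - prior.L_max
        y = prior.a * u
        th = np.tanh(y)
        return th ** 2 + u * 2.0 * th * (1.0 - th ** 2) * prior.a
    if x < prior.L_min:
        u = prior.L_min - x
        y = prior.a * u
        th = np.tanh(y)
        return -(th ** 2 + u * 2.0 * th * (1.0 - th ** 2) * prior.a)
    return 0.0


def discrepancy_residual(s_a1, s_a2, s_b1, s_b2) -> float:
    """Right-minus-left difference of paired segment lengths (metres)."""
    return float(
        np.linalg.norm(np.asarray(s_a1, float) - np.asarray(s_a2, float))
        - np.linalg.norm(np.asarray(s_b1, float) - np.asarray(s_b2, float))
    )


def compose_population_prior(mu_M, sigma_M, mu_F, sigma_F):
    """Composite of male/female population distributions.

    Returns the mean of the two means and the root of the summed variances
    (the enclosing spread of the two per-sex distributions).
    """
    if sigma_M < 0 or sigma_F < 0:
        raise ValueError("standard deviations must be nonnegative")
    return (mu_M + mu_F) / 2.0, float(np.sqrt(sigma_M ** 2 + sigma_F ** 2))


def fit_noise_covariance(samples) -> np.ndarray:
    """Maximum-likelihood zero-mean Gaussian covariance of residual samples.

    All residual models here are zero-mean by construction, so no mean is
    estimated: the fit is ``(1/N) sum e e^T``. Rank-deficient sample sets
    get a small diagonal jitter (with a warning).
    """
    E = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = E.shape
    C = (E.T @ E) / n
    if n < d + 1 or np.linalg.matrix_rank(C, tol=1e-12) < d:
        warnings.warn(
            "too few samples for a full-rank covariance; adding diagonal jitter",
            stacklevel=2,
        )
        logger.warning("covariance fit regularized with 1e-12 diagonal jitter")
        C = C + 1e-12 * np.eye(d)
    return C


def load_anthropometry():
    """Packaged population prior tables.

    Returns ``(axis_segment, lengths)`` where ``axis_segment`` maps segment
    names to :class:`AxisSegmentPrior` (radians) and ``lengths`` maps
    femur/tibia/pelvis to :class:`AnthroPrior` with discrepancy sigmas
    attached for the paired femur/tibia segments.
    """
    text = resources.files("kinegraph").joinpath("anthropometry.yaml").read_text()
    raw = yaml.safe_load(text)
    a = raw["window_sharpness"]
    axis_segment = {
        name: AxisSegmentPrior(
            mu=np.deg2rad(v["mu_deg"]), sigma=np.deg2rad(v["sigma_deg"]), segment=name
        )
        for name, v in raw["axis_segment"].items()
    }
    lengths = {}
    for name, v in raw["lengths"].items():
        sigma_D = raw["discrepancy"].get(name, {}).get("sigma")
        lengths[name] = AnthroPrior(
            mu_L=v["mu"], sigma_L=v["sigma"], L_min=v["min"], L_max=v["max"],
            a=a, sigma_D=sigma_D,
        )
    return axis_segment, lengths
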