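"""Differential-geometry primitives for on-manifold state estimation.

Three manifolds are used throughout the package:

* 3-D rotations, stored as 3x3 orthonormal matrices ``R_A^N`` that map
  frame-A vectors into the navigation frame N;
* rigid transforms (:class:`Pose`), a rotation plus a translation in metres;
* unit axes on the sphere S^2, used for static joint hinge axes.

Conventions fixed here and relied on everywhere else:

* rotation retraction is the *right* perturbation ``R <- R @ exp(delta)``;
* pose tangent vectors are 6-vectors ordered rotation-first,
  ``(dtheta, dp)``, with the translation perturbed additively in the
  navigation frame, ``p <- p + dp``;
* the tangent basis of a unit axis is a deterministic orthonormal pair
  built by a Householder-style rule from the largest-magnitude component,
  so sphere retractions are reproducible bit-for-bit across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pose",
    "hat",
    "vee",
    "rot_exp",
    "rot_log",
    "so3_right_jacobian",
    "so3_right_jacobian_inv",
    "reorthonormalize",
    "is_rotation",
    "pose_act",
    "pose_retract",
    "sphere_basis",
    "sphere_retract",
    "manifold_local",
    "rotation_local",
    "sphere_local",
    "random_rotation",
]

_EPS = 1e-12


def hat(w: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix such that ``hat(w) @ v == cross(w, v)``."""
    wx, wy, wz = w
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def vee(W: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat` (antisymmetric part is taken)."""
    return np.array(
        [W[2, 1] - W[1, 2], W[0, 2] - W[2, 0], W[1, 0] - W[0, 1]]
    ) * 0.5


def rot_exp(omega: np.ndarray) -> np.ndarray:
    """Exponential map of SO(3): rotation by ``|omega|`` about ``omega``.

    Uses the Rodrigues formula with a Taylor branch below 1e-8 rad so the
    zero vector maps exactly to the identity.
    """
    omega = np.asarray(omega, dtype=float)
    theta2 = float(omega @ omega)
    W = hat(omega)
    if theta2 < 1e-16:
        # second-order Taylor expansion; exact at omega == 0
        return np.eye(3) + W + 0.5 * (W @ W)
    theta = np.sqrt(theta2)
    return (
        np.eye(3)
        + (np.sin(theta) / theta) * W
        + ((1.0 - np.cos(theta)) / theta2) * (W @ W)
    )


def rot_log(R: np.ndarray) -> np.ndarray:
    """Logarithm map of SO(3); returns the rotation vector with angle in [0, pi].

    The near-pi branch recovers the axis from the diagonal of
    ``(R + I) / 2`` which stays well conditioned where the antisymmetric
    part of ``R`` vanishes.
    """
    R = np.asarray(R, dtype=float)
    trace = float(np.trace(R))
    cos_theta = np.clip((trace - 1.0) * 0.5, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-7:
        # R ~ I + hat(w): first order
        return vee(R)
    if np.pi - theta < 1e-7:
        # Near pi the antisymmetric part is ~0; use R = I + 2*hat(a)^2 sin^2 etc.
        # axis from largest diagonal of (R + I)/2 = a a^T + cos-terms
        A = (R + np.eye(3)) * 0.5
        k = int(np.argmax(np.diag(A)))
        axis = A[:, k] / np.sqrt(max(A[k, k], _EPS))
        axis = axis / np.linalg.norm(axis)
        # fix the sign using the antisymmetric remainder (may be ~0 at exactly pi,
        # in which case either sign is a valid logarithm)
        w = vee(R)
        if float(w @ axis) < 0.0:
            axis = -axis
        return theta * axis
    return theta / (2.0 * np.sin(theta)) * np.array(
        [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
    )


def so3_right_jacobian(omega: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of SO(3): d exp(w + dw) = exp(w) exp(J_r dw)."""
    omega = np.asarray(omega, dtype=float)
    theta2 = float(omega @ omega)
    W = hat(omega)
    if theta2 < 1e-16:
        return np.eye(3) - 0.5 * W + (W @ W) / 6.0
    theta = np.sqrt(theta2)
    return (
        np.eye(3)
        - ((1.0 - np.cos(theta)) / theta2) * W
        + ((theta - np.sin(theta)) / (theta2 * theta)) * (W @ W)
    )


def so3_right_jacobian_inv(omega: np.ndarray) -> np.ndarray:
    """Inverse right Jacobian of SO(3)."""
    omega = np.asarray(omega, dtype=float)
    theta2 = float(omega @ omega)
    W = hat(omega)
    if theta2 < 1e-16:
        return np.eye(3) + 0.5 * W + (W @ W) / 12.0
    theta = np.sqrt(theta2)
    cot_half = np.cos(0.5 * theta) / np.sin(0.5 * theta)
    return (
        np.eye(3)
        + 0.5 * W
        + (1.0 / theta2 - 0.5 * cot_half / theta) * (W @ W)
    )


def reorthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix back onto SO(3) (polar projection)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(U @ Vt))
    return U @ D @ Vt


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    return (
        R.shape == (3, 3)
        and np.allclose(R.T @ R, np.eye(3), atol=tol)
        and np.linalg.det(R) > 0.0
    )


@dataclass
class Pose:
    """Rigid transform: ``rotation`` in SO(3), ``translation`` in metres.

    Acting on a point gives ``rotation @ point + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def act(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point, dtype=float) + self.translation

    def compose(self, other: "Pose") -> "Pose":
        return Pose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Pose":
        Rt = self.rotation.T
        return Pose(Rt, -Rt @ self.translation)


def pose_act(X: Pose, p: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to a point: ``R p + t``."""
    return X.act(p)


def pose_retract(X: Pose, delta: np.ndarray) -> Pose:
    """Retract a 6-vector ``(dtheta, dp)``: right-perturb R, add dp to t."""
    delta = np.asarray(delta, dtype=float)
    return Pose(X.rotation @ rot_exp(delta[:3]), X.translation + delta[3:])


def sphere_basis(r: np.ndarray) -> np.ndarray:
    """Deterministic 3x2 orthonormal basis of the tangent plane at unit axis r.

    The helper vector is the coordinate axis of the *smallest* magnitude
    component of r (ties broken by lowest index), which keeps the basis far
    from degeneracy and is reproducible across runs.
    """
    r = np.asarray(r, dtype=float)
    k = int(np.argmin(np.abs(r)))
    e = np.zeros(3)
    e[k] = 1.0
    b1 = np.cross(r, e)
    b1 = b1 / np.linalg.norm(b1)
    b2 = np.cross(r, b1)
    return np.column_stack([b1, b2])


def sphere_retract(r: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Exponential-map retraction on S^2 using the deterministic tangent basis.

    ``delta = (0, 0)`` returns ``r`` exactly; the geodesic distance moved is
    ``|delta|``.
    """
    r = np.asarray(r, dtype=float)
    delta = np.asarray(delta, dtype=float)
    theta = float(np.linalg.norm(delta))
    if theta == 0.0:
        return r.copy()
    v = sphere_basis(r) @ delta  # ambient tangent vector, |v| == theta
    out = np.cos(theta) * r + (np.sin(theta) / theta) * v
    return out / np.linalg.norm(out)


def rotation_local(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Tangent vector v with ``Ra @ rot_exp(v) == Rb`` (right convention)."""
    return rot_log(Ra.T @ Rb)


def sphere_local(ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Tangent coordinates of rb at ra (inverse of :func:`sphere_retract`).

    Raises ``ValueError`` for an antipodal pair, where the direction of the
    connecting geodesic is ambiguous and the caller must decide a sign.
    """
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    c = float(np.clip(ra @ rb, -1.0, 1.0))
    if c < -1.0 + 1e-12:
        raise ValueError("antipodal unit axes: geodesic direction is ambiguous")
    theta = np.arccos(c)
    if theta < 1e-12:
        return np.zeros(2)
    v = rb - c * ra  # ambient tangent direction
    v = v / np.linalg.norm(v)
    return theta * (sphere_basis(ra).T @ v)


def manifold_local(a, b) -> np.ndarray:
    """Generic local-coordinates map: retract(a, manifold_local(a, b)) == b.

    Dispatches on type: Pose, 3x3 rotation matrix, or unit 3-vector axis.
    """
    if isinstance(a, Pose):
        return np.concatenate(
            [rotation_local(a.rotation, b.rotation), b.translation - a.translation]
        )
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape == (3, 3):
        return rotation_local(a, b)
    if a.shape == (3,):
        return sphere_local(a, b)
    raise TypeError(f"unsupported manifold element of shape {a.shape}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (axis uniform on sphere, angle from Haar-ish draw)."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
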