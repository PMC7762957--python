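"""Rigid-body geometry: superposition, RMSD and screw (Chasles) decomposition.

Every rigid displacement of a body can be written as a rotation about an
axis in space plus a translation along that axis (a screw motion).  Domain
movements between conformational snapshots of a protein are summarised this
way: the screw angle is the interdomain rotation and the axis is the
mechanical hinge axis.

The least-squares superposition is solved with the quaternion form of the
orthogonal Procrustes problem (Horn's method): the optimal rotation is the
eigenvector of a 4x4 symmetric matrix with the largest eigenvalue.  Unlike
the plain SVD solution this never returns a reflection, and it is well
behaved for nearly degenerate (e.g. close to collinear) point sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "ScrewMotion",
    "InsufficientPointsError",
    "superpose",
    "to_screw",
    "from_screw",
    "apply",
]


class InsufficientPointsError(ValueError):
    """Raised when fewer than three point pairs are supplied."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, acting as ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees from the matrix trace."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ScrewMotion:
    """Chasles decomposition of a rigid transform.

    ``axis_point`` is the point on the axis closest to the origin;
    ``pitch_translation`` is the signed translation along the axis (A).
    For near-zero rotation the motion is reported as a pure translation
    with the axis along the translation vector.
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    angle: float  # degrees, in [0, 180]
    pitch_translation: float

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n > 0:
            d = d / n
        object.__setattr__(self, "axis_direction", d)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3)
        )


def apply(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ t.rotation.T + t.translation


def superpose(
    coords_mobile: np.ndarray,
    coords_ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Weighted least-squares superposition of paired point sets.

    Returns the transform that maps ``coords_mobile`` onto ``coords_ref``
    (minimising the weighted sum of squared deviations) and the post-fit
    RMSD in the same units as the input.  The rotation is always proper
    (determinant +1).
    """
    P = np.asarray(coords_mobile, dtype=float)
    Q = np.asarray(coords_ref, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be paired (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 paired points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).reshape(n)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative and not all zero")
    wsum = w.sum()
    cp = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    X = P - cp
    Y = Q - cq

    # collinearity check: rank of the weighted covariance of either cloud
    sv = np.linalg.svd(np.sqrt(w)[:, None] * X, compute_uv=False)
    if sv[0] > 0 and sv[1] / sv[0] < 1e-8:
        warnings.warn(
            "point set is (near-)collinear; rotation about the line is "
            "unconstrained",
            RuntimeWarning,
            stacklevel=2,
        )

    # Horn's quaternion method
    M = (w[:, None] * X).T @ Y  # 3x3 correlation
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    q = eigvecs[:, -1]  # quaternion (w, x, y, z) of the largest eigenvalue
    qw, qx, qy, qz = q
    R = np.array(
        [
            [
                1 - 2 * (qy * qy + qz * qz),
                2 * (qx * qy - qz * qw),
                2 * (qx * qz + qy * qw),
            ],
            [
                2 * (qx * qy + qz * qw),
                1 - 2 * (qx * qx + qz * qz),
                2 * (qy * qz - qx * qw),
            ],
            [
                2 * (qx * qz - qy * qw),
                2 * (qy * qz + qx * qw),
                1 - 2 * (qx * qx + qy * qy),
            ],
        ]
    )
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    d = apply(transform, P) - Q
    rmsd = float(np.sqrt((w * (d * d).sum(axis=1)).sum() / wsum))
    return transform, rmsd


_PURE_TRANSLATION_ANGLE = 0.1  # degrees


def to_screw(t: RigidTransform) -> ScrewMotion:
    """Chasles decomposition of a rigid transform into a screw motion."""
    angle = t.angle_deg
    if angle < _PURE_TRANSLATION_ANGLE:
        tr = t.translation
        norm = np.linalg.norm(tr)
        direction = tr / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        return ScrewMotion(direction, np.zeros(3), angle, float(norm))

    R = t.rotation
    # rotation axis: for generic angles from the skew-symmetric part; near
    # 180 degrees that part vanishes, so fall back to the +1 eigenvector
    if angle < 179.0:
        axis = np.array(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        )
        axis /= np.linalg.norm(axis)
    else:
        eigvals, eigvecs = np.linalg.eig(R)
        idx = int(np.argmin(np.abs(eigvals - 1.0)))
        axis = np.real(eigvecs[:, idx])
        axis /= np.linalg.norm(axis)
        # fix the sign convention so the angle stays in [0, 180]: choose the
        # sign for which recomposition matches (degenerate only at exactly 180)
        test = _rotation_about(axis, angle)
        if not np.allclose(test, R, atol=1e-6):
            axis = -axis

    pitch = float(t.translation @ axis)
    t_perp = t.translation - pitch * axis
    # axis point c solves (I - R) c = t_perp with c perpendicular to axis;
    # append the constraint row and solve in the least-squares sense
    A = np.vstack([np.eye(3) - R, axis[None, :]])
    b = np.concatenate([t_perp, [0.0]])
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    return ScrewMotion(axis, c, angle, pitch)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def from_screw(s: ScrewMotion) -> RigidTransform:
    """Recompose a screw motion into the equivalent rigid transform."""
    if s.angle < _PURE_TRANSLATION_ANGLE:
        return RigidTransform(np.eye(3), s.pitch_translation * s.axis_direction)
    R = _rotation_about(s.axis_direction, s.angle)
    # x -> R (x - c) + c + pitch * a
    t = s.axis_point - R @ s.axis_point + s.pitch_translation * s.axis_direction
    return RigidTransform(R, t)
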