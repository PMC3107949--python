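"""Rigid-body geometry primitives: rotations, poses, and planar angle helpers.

Conventions used throughout the package (right foot):

* right-handed frame, units mm;
* ``+X`` anterior (heel to toes), ``+Y`` superior, ``+Z`` lateral
  (medial is ``-Z``); the ground plane is ``Y = 0``.

Rotations are carried as 3x3 proper orthogonal matrices; increments are
parametrized as rotation vectors (axis-angle, radians) composed onto a
reference rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose",
    "rotvec_to_matrix",
    "so3_left_jacobian",
    "quat_wxyz_from_matrix",
    "matrix_from_quat_wxyz",
    "project_onto_plane",
    "signed_planar_angle",
    "unsigned_planar_angle",
]


def rotvec_to_matrix(rv: np.ndarray) -> np.ndarray:
    """Rodrigues formula: rotation vector (radians) -> 3x3 rotation matrix."""
    rv = np.asarray(rv, dtype=float)
    angle = float(np.linalg.norm(rv))
    K = np.array(
        [
            [0.0, -rv[2], rv[1]],
            [rv[2], 0.0, -rv[0]],
            [-rv[1], rv[0], 0.0],
        ]
    )
    if angle < 1e-12:
        # second-order series keeps the map smooth through zero
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(angle) / angle
    b = (1.0 - np.cos(angle)) / angle**2
    return np.eye(3) + a * K + b * (K @ K)


def so3_left_jacobian(rv: np.ndarray) -> np.ndarray:
    """Left Jacobian J_l of SO(3) at rotation vector ``rv``.

    Satisfies d/dtheta [ exp([theta]x) v ] = -[exp([theta]x) v]x @ J_l(theta),
    which is what the energy gradient needs to map point forces into
    rotation-coordinate gradients.
    """
    rv = np.asarray(rv, dtype=float)
    angle = float(np.linalg.norm(rv))
    K = np.array(
        [
            [0.0, -rv[2], rv[1]],
            [rv[2], 0.0, -rv[0]],
            [-rv[1], rv[0], 0.0],
        ]
    )
    if angle < 1e-8:
        return np.eye(3) + 0.5 * K + (K @ K) / 6.0
    a = (1.0 - np.cos(angle)) / angle**2
    b = (angle - np.sin(angle)) / angle**3
    return np.eye(3) + a * K + b * (K @ K)


def quat_wxyz_from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation matrix -> unit quaternion, order (w, x, y, z), w >= 0."""
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(R[i, i] - R[j, j] - R[k, k] + 1.0, 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def matrix_from_quat_wxyz(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) -> rotation matrix."""
    w, x, y, z = np.asarray(q, dtype=float) / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class Pose:
    """Rigid-body pose: position (mm) plus proper rotation matrix."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise ValueError(f"pose rotation determinant {np.linalg.det(R)!r} != +1")
        if np.abs(R @ R.T - np.eye(3)).max() > tol:
            raise ValueError("pose rotation is not orthonormal")

    def transform(self, local: np.ndarray) -> np.ndarray:
        """Map local point(s) (mm) into the world frame."""
        local = np.asarray(local, dtype=float)
        return local @ self.rotation.T + self.position

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other (apply ``other`` first)."""
        return Pose(self.rotation @ other.position + self.position, self.rotation @ other.rotation)

    def copy(self) -> "Pose":
        return Pose(self.position.copy(), self.rotation.copy())

    @property
    def quaternion_wxyz(self) -> np.ndarray:
        return quat_wxyz_from_matrix(self.rotation)

    def to_dict(self) -> dict:
        return {
            "position_mm": [float(v) for v in self.position],
            "quaternion_wxyz": [float(v) for v in self.quaternion_wxyz],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(np.array(d["position_mm"]), matrix_from_quat_wxyz(np.array(d["quaternion_wxyz"])))

    @classmethod
    def identity(cls) -> "Pose":
        return cls()


def project_onto_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Component of ``v`` perpendicular to ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, n) * n


def signed_planar_angle(a: np.ndarray, b: np.ndarray, normal: np.ndarray) -> float:
    """Signed angle (degrees) from ``a`` to ``b`` about ``normal``.

    Both vectors are first projected onto the plane with the given normal;
    positive sense follows the right-hand rule around ``normal``.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ap = project_onto_plane(a, n)
    bp = project_onto_plane(b, n)
    la, lb = np.linalg.norm(ap), np.linalg.norm(bp)
    if la < 1e-12 or lb < 1e-12:
        raise ValueError("vector is (numerically) parallel to the projection normal")
    cross = np.cross(ap, bp)
    return float(np.degrees(np.arctan2(np.dot(cross, n), np.dot(ap, bp))))


def unsigned_planar_angle(a: np.ndarray, b: np.ndarray, normal: np.ndarray) -> float:
    """Unsigned in-plane angle (degrees, in [0, 180])."""
    return abs(signed_planar_angle(a, b, normal))
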