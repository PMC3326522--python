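"""Rigid-body primitives shared by the phantom, fitting and quantification stages.

Conventions (used package-wide):

* Coordinates are in Angstroms, right-handed, with the ring symmetry axis
  along +Z and the top ring at z > 0.
* Euler angles are ZYZ, intrinsic, in degrees; the final Z rotation is the
  in-plane rotation of a projection image.
* Rotations are represented as 3x3 matrices acting on column vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle_deg`` about a unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isclose(n, 1.0, atol=1e-9):
        raise ValueError(f"hinge/rotation axis must be unit length, got |a|={n}")
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def euler_zyz_matrix(phi_deg: float, theta_deg: float, psi_deg: float) -> np.ndarray:
    """Intrinsic ZYZ rotation matrix R = Rz(phi) @ Ry(theta) @ Rz(psi)."""
    return Rotation.from_euler(
        "ZYZ", [phi_deg, theta_deg, psi_deg], degrees=True
    ).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """Affine map x -> R @ x + t."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_point(
        cls, axis: np.ndarray, angle_deg: float, point: np.ndarray
    ) -> "RigidTransform":
        """Rotation about an axis through ``point`` (the point is fixed)."""
        R = rotation_about_axis(axis, angle_deg)
        point = np.asarray(point, dtype=float)
        return cls(R, point - R @ point)

    @classmethod
    def translation(cls, t: np.ndarray) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))


def kabsch(moving: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns the proper rigid transform minimizing the weighted RMSD
    ``|R @ moving + t - target|``.  Standard SVD solution with the
    determinant sign fix to exclude reflections.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need two equally sized sets of >=3 points")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def axis_angle_of(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation axis (unit vector) and angle in degrees, angle in [0, 180]."""
    rv = Rotation.from_matrix(R).as_rotvec()
    angle = np.linalg.norm(rv)
    if angle < 1e-15:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return rv / angle, float(np.rad2deg(angle))
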