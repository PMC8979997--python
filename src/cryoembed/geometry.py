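"""Angle conventions and exact conversions on SO(3) and the unit sphere.

A projection's orientation is the rotation carrying the image's local frame
into the world frame.  We use the intrinsic ZYZ Euler convention

    R(alpha, beta, gamma) = Rz(alpha) @ Ry(beta) @ Rz(gamma)

whose columns are (local X-axis, local Y-axis, normal).  Under this convention
the normal vector is (sin b cos a, sin b sin a, cos b) -- i.e. the spherical
point with azimuth ``alpha`` and polar angle ``beta`` -- and applying
``Ry(-beta) @ Rz(-alpha)`` to the local X-axis yields (cos g, sin g, 0), the
identity used downstream to read the in-plane angle off the second embedding.

All angles are radians internally; degrees appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "EulerAngles",
    "OrientationSet",
    "wrap_angle",
    "normal_from_angles",
    "sphere_points_to_xyz",
    "xyz_to_sphere_points",
    "euler_to_rotation",
    "rotation_to_euler",
    "geodesic_distance",
    "dihedral_from_orientations",
    "pairwise_geodesic",
    "rot_z",
    "rot_y",
]


def wrap_angle(a):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(a, TWO_PI)


def rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class EulerAngles:
    """ZYZ Euler triple (alpha, beta, gamma), stored wrapped.

    ``beta`` is the tilt of the normal from the +Z axis and must lie in
    [0, pi]; ``alpha`` (azimuth) and ``gamma`` (in-plane rotation) are wrapped
    to [0, 2*pi).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        object.__setattr__(self, "alpha", float(wrap_angle(self.alpha)))
        object.__setattr__(self, "gamma", float(wrap_angle(self.gamma)))
        b = float(self.beta)
        if not (-1e-12 <= b <= np.pi + 1e-12):
            raise ValueError(f"beta must lie in [0, pi], got {b}")
        object.__setattr__(self, "beta", float(min(max(b, 0.0), np.pi)))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass
class OrientationSet:
    """Per-image Euler angles as an (n, 3) array of (alpha, beta, gamma)."""

    angles: np.ndarray  # (n, 3) radians

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("angles must be (n, 3)")
        a = a.copy()
        a[:, 0] = wrap_angle(a[:, 0])
        a[:, 2] = wrap_angle(a[:, 2])
        if np.any(a[:, 1] < -1e-9) or np.any(a[:, 1] > np.pi + 1e-9):
            raise ValueError("beta values must lie in [0, pi]")
        a[:, 1] = np.clip(a[:, 1], 0.0, np.pi)
        self.angles = a

    @property
    def n(self) -> int:
        return self.angles.shape[0]

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> EulerAngles:
        return EulerAngles(*self.angles[i])

    def matrices(self) -> np.ndarray:
        """(n, 3, 3) stack of rotation matrices."""
        return np.stack([euler_to_rotation(EulerAngles(*row)) for row in self.angles])

    def normals(self) -> np.ndarray:
        """(n, 3) unit normal vectors."""
        return normal_from_angles(self.angles[:, 0], self.angles[:, 1])

    def xaxes(self) -> np.ndarray:
        """(n, 3) unit local X-axis vectors."""
        return self.matrices()[:, :, 0]

    @classmethod
    def from_matrices(cls, mats: np.ndarray) -> "OrientationSet":
        rows = [rotation_to_euler(m).as_tuple() for m in np.asarray(mats, dtype=float)]
        return cls(np.array(rows))


def normal_from_angles(alpha, beta):
    """Unit vector(s) (sin b cos a, sin b sin a, cos b); broadcasts."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    sb = np.sin(beta)
    v = np.stack([sb * np.cos(alpha), sb * np.sin(alpha), np.cos(beta)], axis=-1)
    return v


def sphere_points_to_xyz(alphas, betas) -> np.ndarray:
    """(n, 2) spherical coordinates -> (n, 3) unit vectors."""
    return normal_from_angles(alphas, betas)


def xyz_to_sphere_points(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3) unit vectors -> (alphas in [0, 2pi), betas in [0, pi])."""
    xyz = np.asarray(xyz, dtype=float)
    betas = np.arccos(np.clip(xyz[..., 2], -1.0, 1.0))
    alphas = wrap_angle(np.arctan2(xyz[..., 1], xyz[..., 0]))
    return alphas, betas


def euler_to_rotation(e: EulerAngles) -> np.ndarray:
    """ZYZ rotation matrix; columns are (local X, local Y, normal)."""
    return rot_z(e.alpha) @ rot_y(e.beta) @ rot_z(e.gamma)


_GIMBAL_EPS = 1e-10


def rotation_to_euler(r: np.ndarray) -> EulerAngles:
    """Invert :func:`euler_to_rotation`.

    At the gimbal degeneracy (beta in {0, pi}) alpha is set to 0 and the full
    in-plane angle is reported in gamma.  Raises on improper (det < 0)
    matrices since a mirror has no Euler-triple representation here.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    det = np.linalg.det(r)
    if det < 0:
        raise ValueError("improper rotation (det < 0): mirror matrices carry no Euler angles")
    c = np.clip(r[2, 2], -1.0, 1.0)
    beta = float(np.arccos(c))
    sb = np.sqrt(max(0.0, 1.0 - c * c))
    if sb > _GIMBAL_EPS:
        alpha = np.arctan2(r[1, 2], r[0, 2])
        gamma = np.arctan2(r[2, 1], -r[2, 0])
    elif c > 0:  # beta == 0: R = Rz(alpha + gamma)
        alpha = 0.0
        gamma = np.arctan2(r[1, 0], r[0, 0])
    else:  # beta == pi: with alpha := 0, R = Ry(pi) Rz(gamma)
        alpha = 0.0
        gamma = np.arctan2(r[1, 0], r[1, 1])
    return EulerAngles(alpha, beta, gamma)


def geodesic_distance(p, q) -> np.ndarray:
    """Great-circle distance between unit vectors (or broadcastable stacks)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dot = np.clip(np.sum(p * q, axis=-1), -1.0, 1.0)
    return np.arccos(dot)


def dihedral_from_orientations(ei: EulerAngles, ej: EulerAngles) -> float:
    """Angle between the two projection planes = angle between normals."""
    ni = normal_from_angles(ei.alpha, ei.beta)
    nj = normal_from_angles(ej.alpha, ej.beta)
    return float(geodesic_distance(ni, nj))


def pairwise_geodesic(xyz: np.ndarray) -> np.ndarray:
    """(n, n) matrix of great-circle distances between rows of ``xyz``."""
    g = np.clip(xyz @ xyz.T, -1.0, 1.0)
    return np.arccos(g)
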