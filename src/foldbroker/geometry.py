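"""Low-level vector geometry: bonds, angles, dihedrals, rigid transforms.

All angles are in radians at this level; degree/radian conversion happens at
the public :mod:`foldbroker.kinematics` boundary.  Coordinates are plain
``(…, 3)`` float64 arrays in Ångström.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "bond_length",
    "bond_angle",
    "dihedral",
    "place_atom",
    "RigidTransform",
    "stub_frame",
    "superpose_rmsd",
]


def bond_length(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(b - a))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians, in [0, pi]. Raises on degenerate geometry."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("bond angle undefined: coincident atoms")
    cosang = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in radians, IUPAC convention (trans = pi).

    Symmetric under reversal: dihedral(a,b,c,d) == dihedral(d,c,b,a).
    """
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: collinear atoms")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return float(np.arctan2(y, x))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d from the three reference atoms a, b, c (NeRF extension).

    The returned point satisfies |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion, with `angle`/`torsion` in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("cannot place atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation between two local frames (the value of a jump).

    Composition convention: ``(self @ other).apply(x) == self.apply(other.apply(x))``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and a 3-vector")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation) -> "RigidTransform":
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    def rotvec_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        r = self.rotation
        return bool(
            np.allclose(r @ r.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < tol
        )

    def distance(self, other: "RigidTransform") -> float:
        """Crude metric: max of rotation-matrix and translation deviations."""
        return max(
            float(np.abs(self.rotation - other.rotation).max()),
            float(np.abs(self.translation - other.translation).max()),
        )

    # rb1-rb3: translation (Å); rb4-rb6: rotation-vector components (degrees)
    def rb_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotvec_deg()])

    @classmethod
    def from_rb_vector(cls, rb: np.ndarray) -> "RigidTransform":
        rb = np.asarray(rb, dtype=float)
        return cls.from_rotvec_deg(rb[3:6], rb[0:3])


def stub_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> RigidTransform:
    """Local orthonormal frame of a residue, from its N, CA, C atoms.

    Origin at CA, x toward C, y the component of (N - CA) orthogonal to x,
    z completing the right-handed set.
    """
    x = c - ca
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("degenerate stub: CA and C coincide")
    x = x / nx
    y = (n - ca) - np.dot(n - ca, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("degenerate stub: N, CA, C collinear")
    y = y / ny
    z = np.cross(x, y)
    return RigidTransform(np.column_stack([x, y, z]), ca.astype(float))


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray, subset=None) -> float:
    """Minimal RMSD between two coordinate sets over rigid transforms (Kabsch).

    `subset` optionally selects rows (same indices into both arrays).
    Symmetric in its arguments.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if subset is not None:
        idx = np.asarray(list(subset))
        a = a[idx]
        b = b[idx]
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    diff = a0 - rot.apply(b0)
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))
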