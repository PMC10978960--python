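"""Rigid-body geometry primitives: Kabsch superposition, RMSD, dihedrals.

All coordinates are in Angstrom, arrays are ``(n, 3)`` float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid superposition mapping A onto B: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_points(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) coordinates, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("non-finite coordinates")
    return a


def superpose_kabsch(coords_a, coords_b) -> Superposition:
    """Optimal proper rotation + translation of A onto B (Kabsch, SVD).

    Reflections are excluded (the rotation determinant is +1).  Requires
    at least 3 paired points that are not all collinear.
    """
    A = _as_points(coords_a)
    B = _as_points(coords_b)
    if A.shape != B.shape:
        raise GeometryError("coordinate sets must have equal length")
    n = A.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 paired points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    # collinear points leave the rotation about the line undetermined
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2 or np.linalg.matrix_rank(Bc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) geometry")
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = Ac @ R.T - Bc
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle (degrees, in [0, 180]) of a 3x3 rotation matrix."""
    cos = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise GeometryError("zero rotation axis")
    u = u / norm
    th = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def min_distance(coords_a, coords_b) -> float:
    """Minimum Euclidean distance between two point sets."""
    A = _as_points(coords_a)
    B = _as_points(coords_b)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return float(d.min())


def angle_between_deg(v1, v2) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
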