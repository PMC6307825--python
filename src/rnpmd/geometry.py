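"""Geometric kernels: distances, angles, dihedrals, ring planes, Kabsch.

All lengths in nm, all angles in degrees.  No periodic imaging: inputs are
whole-molecule ensembles as deposited (NMR-style / imaged solute frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Frame, Selection

__all__ = [
    "DihedralSeries",
    "SuperpositionResult",
    "distance",
    "angle",
    "dihedral",
    "ring_plane_normal",
    "plane_angle",
    "kabsch_superpose",
    "superposed_rmsd",
]


class DegenerateGeometryError(ValueError):
    """Geometry is undefined (coincident or collinear atoms)."""


@dataclass
class DihedralSeries:
    """Per-frame values of one named torsion of one residue, degrees."""

    chain_id: str
    residue_index: int
    angle_name: str  # phi, psi, chi1..chi5
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values <= -180.0) | (self.values > 180.0)):
            raise ValueError("angles must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile frame onto a reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # nm
    rmsd: float  # nm, on the fitted selection

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance between atoms *i* and *j* (nm)."""
    return float(np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]))


def angle(frame: Frame, i: int, j: int, k: int) -> float:
    """Angle at vertex *j* of the i–j–k triple, degrees in [0, 180]."""
    a = frame.coordinates[i] - frame.coordinates[j]
    b = frame.coordinates[k] - frame.coordinates[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(frame: Frame, i: int, j: int, k: int, l: int) -> float:
    """Signed IUPAC torsion i–j–k–l, degrees in (−180, 180].

    0° is the cis (eclipsed) arrangement, 180° trans.
    """
    p = frame.coordinates
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms in dihedral computation")
    b2u = b2 / np.linalg.norm(b2)
    # cross(n1, n2) is parallel to b2; its projection carries the sign
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def ring_plane_normal(frame: Frame, ring: Selection) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring atoms.

    The direction (sign) is arbitrary; compare planes with
    :func:`plane_angle`, which folds into [0°, 90°].
    """
    pts = frame.coordinates[ring.as_array()]
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("ring needs at least 3 atoms")
    centered = pts - pts.mean(axis=0)
    # right-singular vector of least variance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12:
        raise DegenerateGeometryError("ring atoms are collinear")
    return vt[2]


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded into [0°, 90°]."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch_superpose(
    mobile: Frame, reference: Frame, on: Selection
) -> SuperpositionResult:
    """Least-squares rigid-body fit of *mobile* onto *reference*.

    Uses the Kabsch SVD algorithm with determinant correction so the
    rotation is proper (no reflections).  The reported RMSD is computed on
    the fitted selection after superposition.
    """
    idx = on.as_array()
    if len(idx) < 3:
        raise ValueError("superposition needs a selection of >= 3 atoms")
    P = mobile.coordinates[idx]
    Q = reference.coordinates[idx]
    pbar = P.mean(axis=0)
    qbar = Q.mean(axis=0)
    H = (P - pbar).T @ (Q - qbar)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-15:
        raise DegenerateGeometryError("rank-deficient selection for superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qbar - R @ pbar
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def superposed_rmsd(frame_a: Frame, frame_b: Frame, on: Selection) -> float:
    """RMSD (nm) of the selection after optimal superposition of a onto b."""
    return kabsch_superpose(frame_a, frame_b, on).rmsd
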