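"""Vector-geometry primitives shared by all interaction detectors.

Distances are in angstroms, angles in degrees. Coordinates are plain
Euclidean: trajectories are expected to be wrapped/centered beforehand,
no minimum-image convention is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when a geometric quantity is undefined for the given points."""


@dataclass(frozen=True)
class RingDescriptor:
    """Best-fit plane description of an aromatic ring system.

    The normal's sign depends on construction order and is arbitrary;
    consumers must fold angles symmetrically (theta vs 180-theta).
    """

    member_atom_indices: tuple[int, ...]
    centroid: np.ndarray  # 3-vector, angstrom
    normal: np.ndarray  # unit 3-vector


def distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two points in angstrom."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


def angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] so that roundoff
    on (anti)parallel vectors never produces NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle undefined for zero vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed IUPAC torsion angle a-b-c-d about the b-c axis, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n_b2 = np.linalg.norm(b2)
    if n_b2 == 0.0:
        raise DegenerateGeometryError("dihedral undefined: b and c coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError("dihedral undefined: collinear points")
    # atan2 formulation is numerically stable near 0 and 180 degrees
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / n_b2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def ring_descriptor(
    coords: np.ndarray, member_indices: Sequence[int] | None = None
) -> RingDescriptor:
    """Centroid and best-fit plane normal of >=3 non-collinear points.

    The normal is the unit eigenvector of the smallest eigenvalue of the
    centered covariance matrix (total least squares plane fit).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise DegenerateGeometryError("ring requires >=3 points of dimension 3")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # SVD of the centered coordinates: last right-singular vector spans the
    # direction of least variance, i.e. the plane normal.
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:  # rank < 2: points are collinear
        raise DegenerateGeometryError("ring points are collinear")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    idx = tuple(member_indices) if member_indices is not None else tuple(range(len(coords)))
    return RingDescriptor(member_atom_indices=idx, centroid=centroid, normal=normal)


def folded_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between vectors folded to [0, 90] (sign-independent)."""
    a = angle(u, v)
    return a if a <= 90.0 else 180.0 - a
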