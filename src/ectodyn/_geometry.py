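"""Low-level rigid-body and internal-coordinate geometry.

Shared by the metrics module (superposition, dihedrals) and the synthetic
generator (NeRF chain extension).  All angles in these helpers are radians;
public package interfaces convert to degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "apply_transform",
    "dihedral",
    "angle_between",
    "rotation_about_axis",
    "place_atom_nerf",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition (Kabsch, via SVD).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` minimises the
    (weighted) RMSD to ``reference``.  A reflection in the SVD solution is
    corrected to enforce det(R) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    # collinearity check: rank of the centered reference point cloud
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = (w[:, None] * mob_c).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    com_mob = (w[:, None] * mobile).sum(axis=0)
    com_ref = (w[:, None] * reference).sum(axis=0)
    t = com_ref - R @ com_mob
    diff = (mob_c @ R.T) - ref_c
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ R.T + t


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors, radians in [0, pi]."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3, radians in (-pi, pi], IUPAC sign."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.arctan2(-y, x))
    return np.pi if ang == -np.pi else ang


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, radians."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def place_atom_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                    bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension reference-frame atom placement.

    Places atom D such that |C-D| = ``bond``, the B-C-D angle equals
    ``angle`` and the A-B-C-D torsion equals ``torsion`` (both radians).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
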