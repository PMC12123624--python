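"""Internal-coordinate values and analytic Cartesian gradients.

Used by the toy labeler (bonded terms) and by restrained optimization
(dihedral restraints).  Conventions: angles in radians internally; the
dihedral of atoms (0,1,2,3) is the signed angle between the planes
(0,1,2) and (1,2,3), in (−π, π], measured with the IUPAC sign convention
(cis = 0).
"""

from __future__ import annotations

import numpy as np


def angle_and_grad(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Angle at vertex p1 spanned by p0 and p2, with gradients.

    Returns (theta, (g0, g1, g2)) where g_a = dθ/dp_a.
    """
    u = p0 - p1
    v = p2 - p1
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos_t = np.clip(uh @ vh, -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = max(np.sqrt(1.0 - cos_t * cos_t), 1e-10)
    g0 = (cos_t * uh - vh) / (nu * sin_t)
    g2 = (cos_t * vh - uh) / (nv * sin_t)
    g1 = -(g0 + g2)
    return theta, (g0, g1, g2)


def dihedral_and_grad(p0, p1, p2, p3):
    """Signed dihedral angle of the chain p0-p1-p2-p3 with gradients.

    Returns (phi, (g0, g1, g2, g3)).  Uses the standard bond-normal
    formulation; gradients are exact away from the colinear degeneracy.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.dot(np.cross(m, n), b2) / nb2, np.dot(m, n))
    m2 = max(m @ m, 1e-18)
    n2 = max(n @ n, 1e-18)
    g0 = -nb2 / m2 * m
    g3 = nb2 / n2 * n
    s12 = (b1 @ b2) / (nb2 * nb2)
    s32 = (b3 @ b2) / (nb2 * nb2)
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1.0 + s32) * g3
    return phi, (g0, g1, g2, g3)


def dihedral(positions: np.ndarray, indices) -> float:
    """Dihedral angle in degrees for four atom indices."""
    i, j, k, l = indices
    phi, _ = dihedral_and_grad(positions[i], positions[j],
                               positions[k], positions[l])
    return float(np.degrees(phi))


def wrap_angle_difference(delta_rad: float) -> float:
    """Map an angle difference into (−π, π]."""
    return float(np.arctan2(np.sin(delta_rad), np.cos(delta_rad)))


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of P onto Q (no atom reordering).

    Returns (rmsd, R, t) minimizing ‖(P@Rᵀ + t) − Q‖; proper rotations only.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    P_fit = Pc @ R.T
    rmsd = np.sqrt(np.mean(np.sum((P_fit - Qc) ** 2, axis=1)))
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    return float(rmsd), R, t
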