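"""Small geometric primitives shared by the fixture generators and the
backbone/side-chain reconstruction stage.

All lengths in Å, all angles in degrees at the public surface.  Ideal
peptide geometry constants follow standard values: N-CA 1.458, CA-C 1.525,
C-N 1.329, C=O 1.231, CA-CB 1.53.
"""

from __future__ import annotations

import math

import numpy as np

# ideal bond lengths (Å)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.53

# ideal bond angles (degrees)
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond, angle B-C-D and dihedral
    A-B-C-D (natural extension reference frame)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            -bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = n1 @ n2
    y = m1 @ n2
    return math.degrees(math.atan2(y, x))


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = unit(np.asarray(p1, float) - np.asarray(p2, float))
    v2 = unit(np.asarray(p3, float) - np.asarray(p2, float))
    return math.degrees(math.acos(np.clip(v1 @ v2, -1.0, 1.0)))


def cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB for an L-amino acid, from backbone N, CA, C.

    The CB direction makes the ideal N-CA-CB angle with both backbone
    substituents and the signed volume det[N-CA, C-CA, CB-CA] is positive
    (L chirality).
    """
    b1 = unit(np.asarray(n, float) - ca)
    b2 = unit(np.asarray(c, float) - ca)
    bisector = unit(b1 + b2)
    normal = unit(np.cross(b1, b2))
    gamma = 0.5 * math.acos(np.clip(b1 @ b2, -1.0, 1.0))
    a_coef = -math.cos(math.radians(ANGLE_N_CA_CB)) / math.cos(gamma)
    a_coef = min(a_coef, 1.0)
    b_coef = math.sqrt(max(0.0, 1.0 - a_coef * a_coef))
    direction = -a_coef * bisector + b_coef * normal
    return np.asarray(ca, float) + BOND_CA_CB * unit(direction)


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning point set p onto q.

    Returns (R, centroid_p, centroid_q) such that (p - cp) @ R.T + cq is the
    least-squares superposition of p onto q, with det(R) = +1 enforced.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    return r, cp, cq
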