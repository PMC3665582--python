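"""Low-level vector geometry: torsion angles, internal-coordinate atom
placement (NeRF) and rigid-body superposition.

All angles are in degrees; torsions live in (-180, 180].
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "kabsch",
    "rotate_about_axis",
    "wrap_angle",
]


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (np.asarray(deg) + 180.0) % 360.0 - 180.0
    a = np.where(a == -180.0, 180.0, a)
    return float(a) if np.ndim(deg) == 0 else a


def angle(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Looking down the p1->p2 bond, a clockwise rotation of the far bond
    relative to the near bond is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    # components of b0, b2 perpendicular to b1
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, ang: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = ang and
    dihedral(a,b,c,d) = torsion (degrees).  Natural extension reference
    frame construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang_r = np.radians(ang)
    tor_r = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang_r),
            bond * np.sin(ang_r) * np.cos(tor_r),
            bond * np.sin(ang_r) * np.sin(tor_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (R, t) with target ~= mobile @ R.T + t.  Proper rotation only
    (no reflection).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rotate_about_axis(points: np.ndarray, origin, axis, deg: float) -> np.ndarray:
    """Rotate points about the line through `origin` along `axis` by `deg`
    degrees (right-hand rule)."""
    origin = np.asarray(origin, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    pts = np.asarray(points, float) - origin
    return pts @ R.T + origin
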