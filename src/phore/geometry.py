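"""Rigid-body geometry helpers shared by perception, model building and matching.

All coordinates are in Ångström, float64, shape (n, 3).
"""
from __future__ import annotations

import math

import numpy as np


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` best fits ``target`` in
    the least-squares sense.  Proper rotation only (det(R) = +1).  For 1 or 2
    points the problem is underdetermined; the SVD still yields a valid
    minimiser, which is all the matcher needs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a–vertex–b in degrees."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal display rounding, ties away from zero (0.625 -> 0.63)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
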