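"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the quaternion
superposition is Horn's closed-form method (no SVD), the grid oracle is
a brute-force search over rotations with closed-form translation, and the
cylindrical-merge profile literally builds the union of rotated copies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_rmsd(moving: np.ndarray, target: np.ndarray) -> float:
    """Optimal proper-rotation RMSD via Horn's quaternion eigenproblem."""
    p = moving - moving.mean(axis=0)
    q = target - target.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = (p**2).sum() + (q**2).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / len(p)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def grid_search_rmsd(
    moving: np.ndarray,
    target: np.ndarray,
    n_axes: int = 200,
    n_angles: int = 90,
    refine: bool = True,
) -> float:
    """Brute-force minimum RMSD over proper rotations: coarse search over
    axis/angle with closed-form (centroid) translation, then simplex
    refinement of the rotation vector."""
    mv = moving - moving.mean(axis=0)
    tg = target - target.mean(axis=0)
    axes = _fibonacci_sphere(n_axes)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    rotvecs = (axes[:, None, :] * angles[None, :, None]).reshape(-1, 3)
    mats = Rotation.from_rotvec(rotvecs).as_matrix()
    resid = np.einsum("nij,kj->nki", mats, mv) - tg
    costs = (resid**2).sum(axis=(1, 2))
    best = rotvecs[int(np.argmin(costs))]

    def cost(rv: np.ndarray) -> float:
        r = Rotation.from_rotvec(rv).as_matrix()
        return float(((mv @ r.T - tg) ** 2).sum())

    if refine:
        sol = minimize(cost, best, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 4000})
        value = min(sol.fun, cost(best))
    else:
        value = cost(best)
    return float(np.sqrt(value / len(mv)))


def planar_grid_rmsd(moving: np.ndarray, target: np.ndarray,
                     step_deg: float = 0.01) -> float:
    """Dense in-plane rotation search for z=0 planar point sets."""
    mv = moving - moving.mean(axis=0)
    tg = target - target.mean(axis=0)
    angles = np.radians(np.arange(0.0, 360.0, step_deg))
    c, s = np.cos(angles), np.sin(angles)
    x = np.outer(c, mv[:, 0]) - np.outer(s, mv[:, 1])
    y = np.outer(s, mv[:, 0]) + np.outer(c, mv[:, 1])
    cost = ((x - tg[:, 0]) ** 2 + (y - tg[:, 1]) ** 2).sum(axis=1)
    return float(np.sqrt(cost.min() / len(mv)))


def rotational_merge_profile(
    points: np.ndarray,
    axis_direction: np.ndarray,
    axis_point: np.ndarray,
    bin_width: float,
    n_copies: int = 72,
) -> dict[int, float]:
    """Explicit cylindrical merge: min distance-to-axis per z-bin over the
    union of ``n_copies`` copies rotated about the axis in equal steps."""
    d = np.asarray(axis_direction, float)
    d = d / np.linalg.norm(d)
    union = []
    for k in range(n_copies):
        rot = Rotation.from_rotvec(d * (2 * np.pi * k / n_copies)).as_matrix()
        union.append((points - axis_point) @ rot.T + axis_point)
    merged = np.concatenate(union)
    rel = merged - axis_point
    z = rel @ d
    r = np.linalg.norm(rel - np.outer(z, d), axis=1)
    idx = np.floor(z / bin_width).astype(int)
    out: dict[int, float] = {}
    for i, radius in zip(idx, r):
        out[i] = min(out.get(i, np.inf), float(radius))
    return out


def brute_force_plane_angle(points: np.ndarray, axis_direction: np.ndarray,
                            n_axes: int = 5000) -> float:
    """Plane fit by brute force: the normal minimizing the variance of the
    points along it, searched on a dense direction grid; returns the acute
    angle (deg) between that normal and the axis."""
    centered = points - points.mean(axis=0)
    normals = _fibonacci_sphere(n_axes)
    spread = ((centered @ normals.T) ** 2).sum(axis=0)
    normal = normals[int(np.argmin(spread))]
    d = np.asarray(axis_direction, float)
    d = d / np.linalg.norm(d)
    cosang = abs(float(normal @ d))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
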