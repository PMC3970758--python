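"""Rigid-body least-squares superposition (Kabsch) and RMSD.

The superposition minimizes the sum of squared distances between paired
points over proper rotations and translations; reflections are excluded
(protein chirality must be preserved). This kernel underlies the
cyclic-symmetry deviation statistic in :mod:`ringgeom.symmetry`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

#: singular-value ratio below which a point set is treated as collinear
_RANK_TOL = 1e-9


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rigid transform ``x -> rotation @ x + translation``
    mapping the moving set onto the target, and the residual RMSD (A)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _as_points(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    return arr


def superpose(moving: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``moving`` onto ``target``.

    Both inputs are ``(n, 3)`` arrays with row-wise correspondence,
    ``n >= 3``.  Near-collinear configurations are rejected: the optimal
    rotation about the degenerate axis is then unconstrained and the
    symmetry statistic built on this kernel must not depend on an
    ill-conditioned fit.
    """
    mv = _as_points(moving, "moving")
    tg = _as_points(target, "target")
    if mv.shape != tg.shape:
        raise ValueError(f"length mismatch: {mv.shape[0]} vs {tg.shape[0]}")
    n = mv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")

    mv_c = mv - mv.mean(axis=0)
    tg_c = tg - tg.mean(axis=0)

    h = mv_c.T @ tg_c
    u, s, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(mv_c), np.linalg.norm(tg_c))
    if scale == 0 or s[1] / (s[0] + 1e-300) < _RANK_TOL:
        raise DegenerateGeometryError(
            "point set is (near-)collinear; superposition ill-conditioned"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tg.mean(axis=0) - rot @ mv.mean(axis=0)
    resid = mv_c @ rot.T - tg_c
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between paired point sets in their current frames (no fitting)."""
    pa = _as_points(a, "a")
    pb = _as_points(b, "b")
    if pa.shape != pb.shape:
        raise ValueError(f"length mismatch: {pa.shape[0]} vs {pb.shape[0]}")
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def rotation_axis_angle(rotation: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle (degrees, in [0, 180]) of a proper
    rotation matrix, with the sign convention that the rotation is
    right-handed about the returned axis."""
    rot = np.asarray(rotation, dtype=float)
    tr = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(tr)))
    # antisymmetric part gives sin(theta) * axis
    w = np.array([
        rot[2, 1] - rot[1, 2],
        rot[0, 2] - rot[2, 0],
        rot[1, 0] - rot[0, 1],
    ])
    norm = np.linalg.norm(w)
    if norm > 1e-12:
        axis = w / norm
    else:
        # theta ~ 0 or 180: take the eigenvector of eigenvalue +1
        vals, vecs = np.linalg.eigh((rot + rot.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
    return axis, angle
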