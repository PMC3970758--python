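"""Deviation-from-cyclic-symmetry statistic for oligomeric rings.

An exactly C_n-symmetric ring maps onto itself when its subunit labels
are rotated one step (ABCDEF onto BCDEFA).  The statistic superposes the
concatenated subdomain coordinates of the ring onto those of its one-step
cyclic permutation with a single global least-squares fit; the residual
RMSD is zero iff the ring is exactly C_n about some axis, and grows with
any departure from that symmetry.  The fitted rotation's invariant line
is the ring's pseudo-symmetry (channel) axis and its angle is near
360/n degrees for near-symmetric rings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import ChannelAxis
from .errors import DegenerateGeometryError
from .structures import Assembly, RingDefinition, select_coords
from .superpose import rmsd_fixed, rotation_axis_angle, superpose


@dataclass
class SymmetryReport:
    """Result of the cyclic-permutation superposition of one ring."""

    permutation_rmsd: float
    per_subunit_rmsd: dict[str, float]
    rotation_angle: float
    axis: ChannelAxis
    step: int
    n_atoms_per_chain: int
    residue_numbers: list[int]

    def __str__(self) -> str:  # human-readable one-liner for the CLI
        per = ", ".join(f"{c}:{v:.3f}" for c, v in self.per_subunit_rmsd.items())
        return (
            f"permutation RMSD {self.permutation_rmsd:.3f} A "
            f"(step {self.step}, angle {self.rotation_angle:.2f} deg); "
            f"per-subunit [{per}]"
        )


def _axis_point(rotation: np.ndarray, translation: np.ndarray,
                centroid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invariant (screw) axis of the rigid map x -> R x + t, and the
    projection of ``centroid`` onto it."""
    axis_dir, _ = rotation_axis_angle(rotation)
    t_perp = translation - (translation @ axis_dir) * axis_dir
    # (I - R) p = t_perp has the invariant line as solution set
    p, *_ = np.linalg.lstsq(np.eye(3) - rotation, t_perp, rcond=None)
    point = p + ((centroid - p) @ axis_dir) * axis_dir
    return axis_dir, point


def permutation_rmsd(
    assembly: Assembly,
    ring: RingDefinition,
    step: int = 1,
    atom_name: str = "CA",
    c_face_sign: int = 1,
) -> SymmetryReport:
    """Cyclic-permutation RMSD of a ring over its subdomain selection.

    Chains ``[c1..cn]`` are superposed, as one concatenated point set,
    onto ``[c(1+step)..]`` with wrap-around.  Returns the global RMSD,
    per-chain residuals under the single global fit, and the axis/angle
    of the fitted rotation.
    """
    n = ring.n
    if step % n == 0:
        raise ValueError(f"step {step} is a multiple of ring size {n}")
    coords, numbers = select_coords(assembly, ring, atom_name)
    order = ring.ordered_chains
    permuted = order[step % n:] + order[: step % n]
    moving = np.concatenate([coords[c] for c in order])
    target = np.concatenate([coords[c] for c in permuted])

    result = superpose(moving, target)
    fitted = result.apply(moving)
    m = len(numbers)
    per_subunit = {
        order[i]: rmsd_fixed(fitted[i * m: (i + 1) * m],
                             target[i * m: (i + 1) * m])
        for i in range(n)
    }
    axis_dir, angle = rotation_axis_angle(result.rotation)
    centroid = moving.mean(axis=0)
    axis_dir, point = _axis_point(result.rotation, result.translation, centroid)
    # orient the axis so the declared C-face sign convention is meaningful
    axis = ChannelAxis(direction=axis_dir, point=point, c_face_sign=c_face_sign)
    return SymmetryReport(
        permutation_rmsd=result.rmsd,
        per_subunit_rmsd=per_subunit,
        rotation_angle=angle,
        axis=axis,
        step=step,
        n_atoms_per_chain=m,
        residue_numbers=numbers,
    )


def subunit_pairwise_rmsd_matrix(
    assembly: Assembly,
    ring: RingDefinition,
    atom_name: str = "CA",
) -> pd.DataFrame:
    """n x n matrix of individually fitted subunit-vs-subunit RMSDs —
    a diagnostic for monomer conformational spread (zero diagonal,
    symmetric)."""
    coords, _ = select_coords(assembly, ring, atom_name)
    ids = ring.ordered_chains
    mat = np.zeros((len(ids), len(ids)))
    for i, ci in enumerate(ids):
        for j in range(i + 1, len(ids)):
            try:
                val = superpose(coords[ci], coords[ids[j]]).rmsd
            except DegenerateGeometryError:
                val = np.nan
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=ids, columns=ids)
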