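"""Channel axis and radial profiling of a ring's central channel.

The profile answers the question "how closely does the protein approach
the channel center at each height along the axis": atoms are binned by
axial coordinate and each bin reports the minimum distance from the axis
over its atoms.  Because distance to the axis is invariant under rotation
about the axis, this per-bin radial minimum equals the closest approach
of a full cylindrical merge (the union of all rotated copies of the
structure about the axis), without constructing molecular surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .errors import DegenerateGeometryError, SelectionError
from .structures import Assembly, RingDefinition, select_coords


@dataclass
class ChannelAxis:
    """Oriented channel axis: unit ``direction``, a ``point`` on the axis,
    and ``c_face_sign`` declaring which direction (+1: along ``direction``)
    points toward the C-terminal/ATPase face of the ring."""

    direction: np.ndarray
    point: np.ndarray
    c_face_sign: int = 1

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.point = np.asarray(self.point, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise DegenerateGeometryError("axis direction is zero")
        self.direction = self.direction / norm
        if self.c_face_sign not in (+1, -1):
            raise ValueError("c_face_sign must be +1 or -1")

    def axial_and_radial(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate z and distance-to-axis r of each point."""
        rel = np.atleast_2d(points) - self.point
        z = rel @ self.direction
        perp = rel - np.outer(z, self.direction)
        return z, np.linalg.norm(perp, axis=1)

    @property
    def c_face_direction(self) -> np.ndarray:
        """Unit vector pointing out of the C-terminal face."""
        return self.c_face_sign * self.direction


@dataclass
class RadialProfile:
    """Closest-approach profile along the axis.

    ``bins`` is a list of ``(z_center, min_radius, atom_count)``; empty
    bins carry ``min_radius = None``.
    """

    bins: list[tuple[float, float | None, int]]
    bin_width: float
    selection_label: str = ""

    def occupied(self) -> list[tuple[float, float, int]]:
        return [(z, r, n) for z, r, n in self.bins if n > 0]


def fit_axis(
    assembly: Assembly,
    ring: RingDefinition,
    method: str = "permutation_rotation",
    atom_name: str = "CA",
    c_face_sign: int = 1,
) -> ChannelAxis:
    """Estimate the ring's channel axis.

    ``permutation_rotation``: axis of the rotation fitted by the one-step
    cyclic-permutation superposition (the ring's pseudo-symmetry axis).
    ``inertia``: principal direction of smallest spatial variance of the
    subdomain atom cloud through its centroid — for a flat ring the
    symmetry axis is the direction in which the cloud is thinnest.
    """
    if method == "permutation_rotation":
        from .symmetry import permutation_rmsd

        report = permutation_rmsd(assembly, ring, atom_name=atom_name)
        axis = report.axis
        return ChannelAxis(axis.direction, axis.point, c_face_sign)
    if method == "inertia":
        coords, _ = select_coords(assembly, ring, atom_name)
        cloud = np.concatenate([coords[c] for c in ring.ordered_chains])
        centroid = cloud.mean(axis=0)
        cov = np.cov((cloud - centroid).T)
        vals, vecs = np.linalg.eigh(cov)
        if vals[1] / max(vals[2], 1e-300) < 1e-9:
            raise DegenerateGeometryError("degenerate (near-linear) cloud")
        return ChannelAxis(vecs[:, 0], centroid, c_face_sign)
    raise ValueError(f"unknown axis method {method!r}")


def _gather(assembly: Assembly, selection) -> np.ndarray:
    """Collect coordinates; ``selection`` is a predicate
    ``(chain, residue, atom_name) -> bool`` or None for all atoms."""
    pts = []
    for chain in assembly.chains:
        for res in chain.residues:
            for name, xyz in res.atoms.items():
                if selection is None or selection(chain, res, name):
                    pts.append(xyz)
    if not pts:
        raise SelectionError("selection matched no atoms")
    return np.array(pts)


def radial_profile(
    assembly: Assembly,
    axis: ChannelAxis,
    selection: Callable | None = None,
    bin_width: float = 1.0,
    probe_radius: float = 0.0,
    selection_label: str = "",
) -> RadialProfile:
    """Per-bin minimum distance-to-axis over the selected atoms.

    Atoms are points; ``probe_radius`` (A) is subtracted uniformly from
    each bin's minimum (floored at 0) when an effective clearance for a
    finite probe is wanted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts = _gather(assembly, selection)
    z, r = axis.axial_and_radial(pts)
    idx = np.floor(z / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    bins: list[tuple[float, float | None, int]] = []
    for i in range(lo, hi + 1):
        mask = idx == i
        count = int(mask.sum())
        z_center = (i + 0.5) * bin_width
        if count:
            radius = max(float(r[mask].min()) - probe_radius, 0.0)
            bins.append((z_center, radius, count))
        else:
            bins.append((z_center, None, 0))
    return RadialProfile(bins=bins, bin_width=bin_width,
                         selection_label=selection_label)


def narrowest_point(profile: RadialProfile) -> tuple[float, float]:
    """The occupied bin with minimal radius, as ``(z_center, radius)``.
    Ties resolve to the smallest z."""
    occupied = profile.occupied()
    if not occupied:
        raise SelectionError("profile has no occupied bins")
    best = min(occupied, key=lambda b: (b[1], b[0]))
    return best[0], best[1]


def clearance_vs_reference(
    profile: RadialProfile, reference_diameter: float = 20.0
) -> list[tuple[float, bool]]:
    """Whether a reference cylinder (default 20 A diameter, the footprint
    of B-form duplex DNA) passes each occupied bin: passable iff
    ``min_radius >= reference_diameter / 2``."""
    half = reference_diameter / 2.0
    return [(z, r >= half) for z, r, _ in profile.occupied()]
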