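"""Geometry of single-stranded DNA bound inside a ring.

Four questions about the crystallographic ssDNA are answered here:

* **polarity** — in which angular sense does the 5'->3' nucleotide order
  advance around the channel axis, viewed from a declared face of the
  ring;
* **planarity** — how far the DNA path tilts from the plane perpendicular
  to the channel (0 deg = the DNA circles the ring exactly perpendicular
  to the channel);
* **stretches** — maximal runs of consecutively numbered modeled
  nucleotides (the bound DNA need not be continuous);
* **subunit assignment** — which protein subunit each nucleotide
  contacts, giving the per-subunit binding increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .channel import ChannelAxis
from .errors import DegenerateGeometryError, SelectionError
from .structures import Assembly, RingDefinition

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"


@dataclass
class Nucleotide:
    number: int
    name: str
    ref_point: np.ndarray
    atoms: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class NAPath:
    """Ordered (5'->3', ascending residue number) nucleotide path of one
    nucleic-acid chain, with recorded numbering gaps."""

    nucleotides: list[Nucleotide]
    gaps: list[tuple[int, int]] = field(default_factory=list)
    chain_id: str = ""

    def __post_init__(self) -> None:
        numbers = [nt.number for nt in self.nucleotides]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise SelectionError(
                f"NAPath {self.chain_id}: residue numbers not strictly "
                "increasing (5'->3')"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def ref_points(self) -> np.ndarray:
        return np.array([nt.ref_point for nt in self.nucleotides])

    def reversed(self) -> "NAPath":
        rev = [
            Nucleotide(-nt.number, nt.name, nt.ref_point, nt.atoms)
            for nt in reversed(self.nucleotides)
        ]
        return NAPath(nucleotides=rev, gaps=list(self.gaps),
                      chain_id=self.chain_id)


@dataclass
class PolarityResult:
    sense: str
    net_sweep: float
    view: str


def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angular increments to (-180, 180] degrees."""
    out = np.mod(delta, 360.0)
    out[out > 180.0] -= 360.0
    return out


def polarity(
    path: NAPath,
    axis: ChannelAxis,
    view_from: str = "c_face",
) -> PolarityResult:
    """Angular sense of the 5'->3' nucleotide order about the axis.

    Reference points are projected onto the plane normal to the axis and
    consecutive signed angular increments (each wrapped to (-180, 180])
    are summed.  With the viewing direction pointing from the chosen face
    toward the viewer, a positive net sweep appears counterclockwise and
    a negative one clockwise.
    """
    if view_from not in ("c_face", "n_face"):
        raise ValueError("view_from must be 'c_face' or 'n_face'")
    if len(path) < 3:
        raise SelectionError("polarity needs at least 3 nucleotides")
    toward_viewer = axis.c_face_direction
    if view_from == "n_face":
        toward_viewer = -toward_viewer

    z, r = axis.axial_and_radial(path.ref_points)
    if np.any(r <= 0.1):
        raise DegenerateGeometryError(
            "a nucleotide lies on the channel axis; angular position "
            "undefined"
        )
    # right-handed in-plane basis (e1, e2, toward_viewer)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ toward_viewer) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ toward_viewer) * toward_viewer
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(toward_viewer, e1)

    rel = path.ref_points - axis.point
    angles = np.degrees(np.arctan2(rel @ e2, rel @ e1))
    sweep = float(_wrap_deg(np.diff(angles)).sum())
    sense = COUNTERCLOCKWISE if sweep >= 0 else CLOCKWISE
    return PolarityResult(sense=sense, net_sweep=sweep,
                          view=f"viewed from the {view_from}")


def planarity(path: NAPath, axis: ChannelAxis) -> float:
    """Acute angle (degrees) between the total-least-squares plane of the
    nucleotide reference points and the plane perpendicular to the axis.

    Returned as the angle between the fitted plane's normal and the axis
    direction: 0 deg means the DNA lies exactly perpendicular to the
    channel."""
    if len(path) < 3:
        raise SelectionError("planarity needs at least 3 nucleotides")
    pts = path.ref_points
    centered = pts - pts.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] / (s[0] + 1e-300) < 1e-9:
        raise DegenerateGeometryError("collinear nucleotide path; no plane")
    normal = vt[2]
    cosang = abs(float(normal @ axis.direction))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def segment_stretches(paths: NAPath | list[NAPath]) -> list[int]:
    """Lengths of maximal runs of consecutive residue numbers, pooled over
    the given chains (chains are never merged into one stretch), sorted
    descending."""
    if isinstance(paths, NAPath):
        paths = [paths]
    lengths: list[int] = []
    for path in paths:
        numbers = [nt.number for nt in path.nucleotides]
        if not numbers:
            continue
        run = 1
        for a, b in zip(numbers, numbers[1:]):
            if b == a + 1:
                run += 1
            else:
                lengths.append(run)
                run = 1
        lengths.append(run)
    return sorted(lengths, reverse=True)


def _heavy_coords(atoms: dict[str, np.ndarray]) -> np.ndarray:
    pts = []
    for name, xyz in atoms.items():
        stripped = name.strip().lstrip("0123456789")
        if stripped[:1].upper() == "H":
            continue
        pts.append(xyz)
    return np.array(pts) if pts else np.empty((0, 3))


def assign_nucleotides(
    assembly: Assembly,
    ring: RingDefinition,
    paths: NAPath | list[NAPath],
    contact_cutoff: float = 4.5,
) -> tuple[list[dict], dict[str, int]]:
    """Assign each nucleotide to the protein subunit it contacts most.

    A contact is a heavy-atom pair within ``contact_cutoff`` A.  Ties go
    to the chain earlier in ring order; contact-free nucleotides stay
    unassigned.  Returns the per-nucleotide assignment table and the
    per-subunit nucleotide counts.
    """
    if isinstance(paths, NAPath):
        paths = [paths]
    trees = {}
    for cid in ring.ordered_chains:
        chain = assembly.chain(cid)
        pts = [
            xyz
            for res in chain.residues if not res.het
            for xyz in [_heavy_coords(res.atoms)] if len(xyz)
        ]
        coords = np.concatenate(pts) if pts else np.empty((0, 3))
        trees[cid] = cKDTree(coords) if len(coords) else None

    assignments: list[dict] = []
    counts = {cid: 0 for cid in ring.ordered_chains}
    for path in paths:
        for nt in path.nucleotides:
            heavy = _heavy_coords(nt.atoms)
            if heavy.size == 0:
                heavy = nt.ref_point[None, :]
            best_chain, best_count = None, 0
            for cid in ring.ordered_chains:
                tree = trees[cid]
                if tree is None:
                    continue
                n_contacts = int(
                    sum(len(hits) for hits in
                        tree.query_ball_point(heavy, contact_cutoff))
                )
                if n_contacts > best_count:
                    best_chain, best_count = cid, n_contacts
            assignments.append(
                {
                    "dna_chain": path.chain_id,
                    "nucleotide": nt.number,
                    "base": nt.name,
                    "assigned_chain": best_chain,
                    "n_contacts": best_count,
                }
            )
            if best_chain is not None:
                counts[best_chain] += 1
    return assignments, counts


def full_occupancy_capacity(ring_size: int, per_subunit_increment: int) -> int:
    """Nucleotides bound if every subunit engages DNA at the consistent
    per-subunit increment (e.g. 6 subunits x 4 nt = 24)."""
    if ring_size <= 0 or per_subunit_increment <= 0:
        raise ValueError("ring_size and per_subunit_increment must be "
                         "positive integers")
    return int(ring_size) * int(per_subunit_increment)
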