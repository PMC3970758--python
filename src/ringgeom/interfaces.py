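"""Intersubunit probe distances and DNA-engagement classification.

A single Calpha-Calpha distance between a probe residue on one subunit
and a partner residue on its neighbor (for PfMCM: R201 of one subunit to
E127 of the counterclockwise subunit) tracks how tightly two subunits
approach each other at the ssDNA-binding interface.  Interfaces with a
short probe distance bind ssDNA; long ones do not.  The default
thresholds are 7.5 A (engaged, strict <) and 8.4 A (disengaged,
strict >); distances between — including values exactly on either
threshold — are classified intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AtomLookupError, SelectionError
from .structures import Assembly, RingDefinition

ENGAGED = "engaged"
INTERMEDIATE = "intermediate"
DISENGAGED = "disengaged"


@dataclass
class ProbeSpec:
    """The interface metric: residue/atom on subunit i, residue/atom on
    its neighbor, which neighbor, and the two class thresholds (A)."""

    residue_a: int = 201
    atom_a: str = "CA"
    residue_b: int = 127
    atom_b: str = "CA"
    neighbor_direction: str = "counterclockwise"
    tau_engaged: float = 7.5
    tau_disengaged: float = 8.4

    def __post_init__(self) -> None:
        if not 0 < self.tau_engaged <= self.tau_disengaged:
            raise ValueError(
                "thresholds must satisfy 0 < tau_engaged <= tau_disengaged"
            )
        if self.neighbor_direction not in ("counterclockwise", "clockwise"):
            raise ValueError("neighbor_direction must be counterclockwise "
                             "or clockwise")

    def classify(self, distance: float) -> str:
        if distance < self.tau_engaged:
            return ENGAGED
        if distance > self.tau_disengaged:
            return DISENGAGED
        return INTERMEDIATE


@dataclass
class InterfaceRecord:
    subunit_pair: tuple[str, str]
    distance: float
    engagement: str


def probe_distance(
    assembly: Assembly,
    chain_i: str,
    chain_j: str,
    probe: ProbeSpec,
) -> float:
    """Euclidean distance from probe atom A on ``chain_i`` to probe atom B
    on ``chain_j``."""
    try:
        a = assembly.atom(chain_i, probe.residue_a, probe.atom_a)
        b = assembly.atom(chain_j, probe.residue_b, probe.atom_b)
    except AtomLookupError as exc:
        raise AtomLookupError(
            f"interface {chain_i}-{chain_j}: {exc}"
        ) from exc
    return float(np.linalg.norm(a - b))


def classify_ring_interfaces(
    assembly: Assembly,
    ring: RingDefinition,
    probe: ProbeSpec | None = None,
) -> list[InterfaceRecord]:
    """One record per wrap-around consecutive subunit pair in ring order.

    Ring order is counterclockwise viewed from the C-terminal face, so
    the counterclockwise neighbor of chain i is the next chain in the
    list (the previous one for a clockwise probe).
    """
    probe = probe or ProbeSpec()
    order = ring.ordered_chains
    n = len(order)
    shift = 1 if probe.neighbor_direction == "counterclockwise" else -1
    records = []
    for i in range(n):
        ci = order[i]
        cj = order[(i + shift) % n]
        dist = probe_distance(assembly, ci, cj, probe)
        records.append(
            InterfaceRecord(subunit_pair=(ci, cj), distance=dist,
                            engagement=probe.classify(dist))
        )
    return records


def interfaces_table(records: list[InterfaceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain_i": [r.subunit_pair[0] for r in records],
            "chain_j": [r.subunit_pair[1] for r in records],
            "distance": [r.distance for r in records],
            "engagement": [r.engagement for r in records],
        }
    )


def engagement_vs_dna(
    records: list[InterfaceRecord],
    dna_occupancy: dict[tuple[str, str], bool],
    include_intermediate: bool = False,
) -> pd.DataFrame:
    """Join engagement classes with observed DNA occupancy per interface.

    ``dna_occupancy`` maps each subunit pair to whether ssDNA is modeled
    at that interface.  Returns the joined table with a ``concordant``
    column; a row is concordant when engaged interfaces carry DNA and
    disengaged ones do not.  Intermediate interfaces are reported but
    excluded from the concordance count unless ``include_intermediate``.
    The table carries counts in ``df.attrs['n_concordant']`` /
    ``['n_discordant']``.
    """
    missing = [r.subunit_pair for r in records
               if r.subunit_pair not in dna_occupancy]
    if missing:
        raise SelectionError(
            f"dna occupancy missing for interfaces {missing}; the two "
            "inputs must cover the same ring"
        )
    rows = []
    for rec in records:
        has_dna = bool(dna_occupancy[rec.subunit_pair])
        if rec.engagement == INTERMEDIATE and not include_intermediate:
            concordant = None
        else:
            concordant = (rec.engagement == ENGAGED) == has_dna
        rows.append(
            {
                "chain_i": rec.subunit_pair[0],
                "chain_j": rec.subunit_pair[1],
                "distance": rec.distance,
                "engagement": rec.engagement,
                "dna_observed": has_dna,
                "concordant": concordant,
            }
        )
    df = pd.DataFrame(rows)
    judged = df["concordant"].dropna()
    df.attrs["n_concordant"] = int((judged == True).sum())  # noqa: E712
    df.attrs["n_discordant"] = int((judged == False).sum())  # noqa: E712
    return df
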