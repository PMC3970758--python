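"""Interface probe distances and engagement classification."""

import numpy as np
import pytest

from ringgeom import (
    ProbeSpec,
    RingDefinition,
    classify_ring_interfaces,
    engagement_vs_dna,
    probe_distance,
)
from ringgeom.errors import AtomLookupError, SelectionError
from ringgeom.structures import Assembly, Chain, Residue

from conftest import apply_rigid, random_rigid_transform


def _ring_with_distances(distances):
    """A toy n-ring whose i->i+1 probe distances are exactly as given.

    Probe atom A of chain i sits at x_i; probe atom B of chain i+1 sits at
    x_i + d_i along x, far from everything else in y.
    """
    n = len(distances)
    chains = []
    x = 0.0
    a_pos = []
    for i in range(n):
        a_pos.append(x)
        x += distances[i] + 50.0  # spread interfaces far apart
    for i in range(n):
        b_x = a_pos[i - 1] + distances[i - 1]
        chains.append(Chain(
            id=chr(ord("A") + i), polymer_kind="protein",
            residues=[
                Residue(number=127, name="GLU",
                        atoms={"CA": np.array([b_x, 0.0, 0.0])}),
                Residue(number=201, name="ARG",
                        atoms={"CA": np.array([a_pos[i], 0.0, 0.0])}),
            ],
        ))
    ring = RingDefinition(
        ordered_chains=[c.id for c in chains], subdomain_range=(1, 300))
    return Assembly(chains=chains), ring


class TestProbeDistance:
    def test_euclidean_distance(self):
        asm = Assembly(chains=[
            Chain(id="A", residues=[Residue(201, "ARG",
                                            {"CA": np.zeros(3)})]),
            Chain(id="B", residues=[Residue(127, "GLU",
                                            {"CA": np.array([3.0, 4, 0])})]),
        ])
        assert probe_distance(asm, "A", "B", ProbeSpec()) == pytest.approx(5.0)

    def test_swapped_probe_matches_reverse_measurement(self):
        asm = Assembly(chains=[
            Chain(id="A", residues=[
                Residue(127, "GLU", {"CA": np.array([1.0, 1, 1])}),
                Residue(201, "ARG", {"CA": np.zeros(3)}),
            ]),
            Chain(id="B", residues=[
                Residue(127, "GLU", {"CA": np.array([3.0, 4, 0])}),
                Residue(201, "ARG", {"CA": np.array([5.0, 5, 5])}),
            ]),
        ])
        fwd = probe_distance(asm, "A", "B", ProbeSpec())
        swapped = ProbeSpec(residue_a=127, residue_b=201)
        assert probe_distance(asm, "B", "A", swapped) == pytest.approx(fwd)

    def test_missing_atom_names_context(self):
        asm = Assembly(chains=[
            Chain(id="A", residues=[Residue(201, "ARG", {"CA": np.zeros(3)})]),
            Chain(id="B", residues=[Residue(999, "GLY", {"CA": np.ones(3)})]),
        ])
        with pytest.raises(AtomLookupError, match="A-B"):
            probe_distance(asm, "A", "B", ProbeSpec())


class TestClassification:
    def test_threshold_rule_with_default_thresholds(self):
        asm, ring = _ring_with_distances([7.0, 7.6, 9.0])
        records = classify_ring_interfaces(asm, ring)
        assert [r.engagement for r in records] == [
            "engaged", "intermediate", "disengaged"]
        assert [r.distance for r in records] == pytest.approx([7.0, 7.6, 9.0])

    def test_all_engaged_tight_ring(self):
        asm, ring = _ring_with_distances([7.0] * 6)
        records = classify_ring_interfaces(asm, ring)
        assert all(r.engagement == "engaged" for r in records)
        assert len(records) == 6

    @pytest.mark.parametrize("dist,expected", [
        (7.5, "intermediate"),  # strict <: boundary is not engaged
        (8.4, "intermediate"),  # strict >: boundary is not disengaged
    ])
    def test_boundary_values_are_intermediate(self, dist, expected):
        assert ProbeSpec().classify(dist) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ProbeSpec(tau_engaged=9.0, tau_disengaged=8.0)

    def test_scale_consistency(self):
        asm, ring = _ring_with_distances([7.0, 7.6, 9.0])
        scaled = Assembly(chains=[
            Chain(id=c.id, polymer_kind=c.polymer_kind, residues=[
                Residue(r.number, r.name,
                        {k: 2.0 * v for k, v in r.atoms.items()})
                for r in c.residues
            ])
            for c in asm.chains
        ])
        probe = ProbeSpec(tau_engaged=15.0, tau_disengaged=16.8)
        records = classify_ring_interfaces(scaled, ring, probe)
        assert [r.engagement for r in records] == [
            "engaged", "intermediate", "disengaged"]
        assert [r.distance for r in records] == pytest.approx(
            [14.0, 15.2, 18.0])

    def test_records_invariant_under_rigid_motion(self, rng):
        asm, ring = _ring_with_distances([7.0, 7.6, 9.0, 8.0])
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid(asm, rot, trans)
        base = classify_ring_interfaces(asm, ring)
        after = classify_ring_interfaces(moved, ring)
        for a, b in zip(base, after):
            assert b.distance == pytest.approx(a.distance, abs=1e-9)
            assert b.engagement == a.engagement

    def test_sort_then_threshold_matches_direct_classification(self, rng):
        dists = rng.uniform(6.0, 10.0, size=6)
        asm, ring = _ring_with_distances(list(dists))
        records = classify_ring_interfaces(asm, ring)
        probe = ProbeSpec()
        by_sort = sorted(records, key=lambda r: r.distance)
        for rec in by_sort:
            assert rec.engagement == probe.classify(rec.distance)

    def test_clockwise_direction_reverses_pairing(self):
        asm, ring = _ring_with_distances([7.0, 7.6, 9.0])
        ccw = classify_ring_interfaces(asm, ring)
        cw = classify_ring_interfaces(
            asm, ring, ProbeSpec(neighbor_direction="clockwise"))
        assert {r.subunit_pair for r in ccw} == {
            (j, i) for i, j in (r.subunit_pair for r in cw)
        } == {("A", "B"), ("B", "C"), ("C", "A")}


class TestEngagementVsDna:
    def _records(self):
        asm, ring = _ring_with_distances([7.0, 7.6, 9.0, 6.5])
        return classify_ring_interfaces(asm, ring)

    def test_fully_concordant(self):
        records = self._records()
        dna = {("A", "B"): True, ("B", "C"): False, ("C", "D"): False,
               ("D", "A"): True}
        df = engagement_vs_dna(records, dna)
        assert df.attrs["n_discordant"] == 0
        assert df.attrs["n_concordant"] == 3  # intermediate excluded

    def test_discordant_interface_flagged(self):
        records = self._records()
        dna = {("A", "B"): False, ("B", "C"): False, ("C", "D"): False,
               ("D", "A"): True}
        df = engagement_vs_dna(records, dna)
        assert df.attrs["n_discordant"] == 1
        row = df[(df.chain_i == "A")].iloc[0]
        assert row.concordant == False  # noqa: E712

    def test_intermediate_included_on_request(self):
        records = self._records()
        dna = {("A", "B"): True, ("B", "C"): True, ("C", "D"): False,
               ("D", "A"): True}
        df = engagement_vs_dna(records, dna, include_intermediate=True)
        # the intermediate interface carries DNA but is not engaged
        assert df.attrs["n_discordant"] == 1

    def test_ring_mismatch_rejected(self):
        records = self._records()
        with pytest.raises(SelectionError):
            engagement_vs_dna(records, {("A", "B"): True})
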