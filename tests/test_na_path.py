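"""ssDNA path polarity, planarity, stretches and subunit assignment."""

import numpy as np
import pytest

from ringgeom import (
    ChannelAxis,
    NAPath,
    RingDefinition,
    assign_nucleotides,
    full_occupancy_capacity,
    planarity,
    polarity,
    segment_stretches,
)
from ringgeom.errors import DegenerateGeometryError, SelectionError
from ringgeom.na_path import Nucleotide
from ringgeom.synthetic import SyntheticDNASpec, SyntheticRingSpec, make_dna, ring_with_dna

Z_AXIS = ChannelAxis(direction=[0, 0, 1], point=[0, 0, 0], c_face_sign=1)


def _path_at_angles(angles_deg, radius=15.0, z=0.0, numbers=None):
    numbers = numbers or range(1, len(angles_deg) + 1)
    nts = [
        Nucleotide(number=num, name="DT", ref_point=np.array([
            radius * np.cos(np.radians(a)),
            radius * np.sin(np.radians(a)), z,
        ]))
        for num, a in zip(numbers, angles_deg)
    ]
    return NAPath(nucleotides=nts, chain_id="M")


class TestPolarity:
    def test_increasing_angle_is_counterclockwise_from_positive_face(self):
        path = _path_at_angles([0, 30, 60, 90])
        res = polarity(path, Z_AXIS, view_from="c_face")
        assert res.sense == "counterclockwise"
        assert res.net_sweep == pytest.approx(90.0)

    def test_reversed_order_flips_sense_and_sign(self):
        path = _path_at_angles([0, 30, 60, 90])
        res = polarity(path.reversed(), Z_AXIS, view_from="c_face")
        assert res.sense == "clockwise"
        assert res.net_sweep == pytest.approx(-90.0)

    def test_view_from_opposite_face_flips_sense(self):
        path = _path_at_angles([0, 30, 60, 90])
        res = polarity(path, Z_AXIS, view_from="n_face")
        assert res.sense == "clockwise"
        assert res.net_sweep == pytest.approx(-90.0)

    def test_sense_invariant_under_consistent_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        path = _path_at_angles([0, -25, -50, -75, -100])
        base = polarity(path, Z_AXIS)
        rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        trans = rng.normal(scale=30.0, size=3)
        moved = NAPath(nucleotides=[
            Nucleotide(nt.number, nt.name, rot @ nt.ref_point + trans)
            for nt in path.nucleotides
        ], chain_id="M")
        moved_axis = ChannelAxis(direction=rot @ Z_AXIS.direction,
                                 point=rot @ Z_AXIS.point + trans,
                                 c_face_sign=Z_AXIS.c_face_sign)
        res = polarity(moved, moved_axis)
        assert res.sense == base.sense
        assert res.net_sweep == pytest.approx(base.net_sweep, abs=1e-6)

    @pytest.mark.parametrize("n_points", [8, 12, 24, 60])
    def test_closed_circle_sweeps_360(self, n_points):
        angles = np.linspace(0, 360, n_points + 1)  # closed loop
        path = _path_at_angles(list(angles))
        res = polarity(path, Z_AXIS)
        assert res.net_sweep == pytest.approx(360.0, abs=1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(SelectionError):
            polarity(_path_at_angles([0, 30]), Z_AXIS)

    def test_on_axis_point_rejected(self):
        path = _path_at_angles([0, 30, 60])
        path.nucleotides[1] = Nucleotide(2, "DT", np.array([0.0, 0.0, 5.0]))
        with pytest.raises(DegenerateGeometryError):
            polarity(path, Z_AXIS)


class TestPlanarity:
    def test_circle_in_perpendicular_plane_is_zero(self):
        path = _path_at_angles(list(range(0, 360, 30)), z=5.0)
        assert planarity(path, Z_AXIS) == pytest.approx(0.0, abs=1e-9)

    def test_tilted_circle_reports_tilt(self):
        angles = np.radians(np.arange(0, 360, 30))
        pts = np.column_stack([
            15 * np.cos(angles), 15 * np.sin(angles), np.zeros(len(angles))])
        tilt = np.radians(25.0)
        rot_x = np.array([
            [1, 0, 0],
            [0, np.cos(tilt), -np.sin(tilt)],
            [0, np.sin(tilt), np.cos(tilt)],
        ])
        path = NAPath(nucleotides=[
            Nucleotide(i + 1, "DT", rot_x @ p) for i, p in enumerate(pts)
        ])
        assert planarity(path, Z_AXIS) == pytest.approx(25.0, abs=1e-9)

    def test_steep_helix_approaches_90_matching_brute_force(self):
        from _oracles import brute_force_plane_angle

        prev = 0.0
        for radius in (2.0, 0.5, 0.1):
            spec = SyntheticDNASpec(radius=radius, n_nucleotides=12,
                                    angular_step=-30.0, rise_per_nt=5.0)
            path = make_dna(spec)
            angle = planarity(path, Z_AXIS)
            oracle = brute_force_plane_angle(path.ref_points,
                                             Z_AXIS.direction)
            assert angle == pytest.approx(oracle, abs=1.5)  # grid-limited
            assert angle > prev
            prev = angle
        assert prev > 85.0

    def test_collinear_path_rejected(self):
        nts = [Nucleotide(i + 1, "DT", np.array([float(i), 0, 0]))
               for i in range(5)]
        with pytest.raises(DegenerateGeometryError):
            planarity(NAPath(nucleotides=nts), Z_AXIS)


class TestStretches:
    @pytest.mark.parametrize("numbers,expected", [
        (list(range(1, 8)), [7]),
        ([1, 2, 3, 5, 6, 7], [3, 3]),
        ([1, 2, 3, 4] + list(range(6, 17)) + [18, 19, 20, 21],
         [11, 4, 4]),
    ])
    def test_run_segmentation(self, numbers, expected):
        path = _path_at_angles([10.0 * i for i in range(len(numbers))],
                               numbers=numbers)
        assert segment_stretches(path) == expected

    def test_chains_never_merge(self):
        p1 = _path_at_angles([0, 10, 20], numbers=[1, 2, 3])
        p2 = _path_at_angles([40, 50], numbers=[4, 5])
        assert segment_stretches([p1, p2]) == [3, 2]

    def test_total_equals_modeled_nucleotides(self):
        spec = SyntheticDNASpec(n_nucleotides=12, gaps=frozenset({5}))
        path = make_dna(spec)
        assert sum(segment_stretches(path)) == len(path)
        assert segment_stretches(path) == [7, 4]


class TestAssignment:
    @pytest.fixture
    def hosted(self):
        return ring_with_dna(
            SyntheticRingSpec(ring_radius=24.0),
            SyntheticDNASpec(radius=19.0, n_nucleotides=12,
                             angular_step=-30.0),
        )

    def test_every_contacting_nucleotide_assigned_to_a_ring_chain(
            self, hosted, hexamer_ring_def):
        assembly, _, path = hosted
        assignments, counts = assign_nucleotides(
            assembly, hexamer_ring_def, path, contact_cutoff=8.0)
        assigned = [a for a in assignments if a["assigned_chain"]]
        assert assigned, "no contacts at this cutoff"
        assert sum(counts.values()) == len(assigned)

    def test_counts_stable_to_small_cutoff_changes(
            self, hosted, hexamer_ring_def):
        assembly, _, path = hosted
        base = assign_nucleotides(assembly, hexamer_ring_def, path,
                                  contact_cutoff=8.0)[1]
        for cutoff in (7.75, 8.25):
            counts = assign_nucleotides(assembly, hexamer_ring_def, path,
                                        contact_cutoff=cutoff)[1]
            assert counts == base

    def test_tie_goes_to_earlier_ring_chain(self, hexamer_ring_def):
        from ringgeom.structures import Assembly, Chain, Residue

        # one nucleotide exactly between two equal single-atom chains
        chains = [
            Chain(id=c, polymer_kind="protein", residues=[
                Residue(1, "ALA", {"CA": np.array([x, 0.0, 0.0])})])
            for c, x in zip("ABCDEF", [-2.0, 2.0, 50, 60, 70, 80])
        ]
        asm = Assembly(chains=chains)
        path = NAPath(nucleotides=[
            Nucleotide(i, "DT", np.array([0.0, 0.1 * i, 0.0]),
                       atoms={"C1'": np.array([0.0, 0.1 * i, 0.0])})
            for i in (1, 2, 3)
        ], chain_id="M")
        ring = RingDefinition(ordered_chains=list("ABCDEF"),
                              subdomain_range=(1, 30))
        assignments, counts = assign_nucleotides(asm, ring, path,
                                                 contact_cutoff=4.5)
        assert all(a["assigned_chain"] == "A" for a in assignments)
        assert counts["A"] == 3 and counts["B"] == 0


class TestCapacity:
    @pytest.mark.parametrize("n,inc,expected", [
        (6, 4, 24),
        (6, 1, 6),
        (3, 2, 6),
    ])
    def test_product(self, n, inc, expected):
        assert full_occupancy_capacity(n, inc) == expected

    @pytest.mark.parametrize("n,inc", [(0, 4), (6, 0), (-1, 2)])
    def test_non_positive_rejected(self, n, inc):
        with pytest.raises(ValueError):
            full_occupancy_capacity(n, inc)
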