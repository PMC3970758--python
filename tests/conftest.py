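import numpy as np
import pytest

from ringgeom import RingDefinition
from ringgeom.synthetic import (
    SubunitPerturbation,
    SyntheticDNASpec,
    SyntheticRingSpec,
    make_ring,
    ring_with_dna,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hexamer_ring_def():
    return RingDefinition(ordered_chains=list("ABCDEF"),
                          subdomain_range=(1, 30), label="hex")


@pytest.fixture
def exact_c6():
    """Exactly C6-symmetric synthetic hexamer plus its ground truth."""
    return make_ring(SyntheticRingSpec())


@pytest.fixture
def perturbed_c6():
    """Near-C6 hexamer with per-subunit perturbations of mixed kinds."""
    perts = [
        SubunitPerturbation(radial_shift=1.0),
        SubunitPerturbation(tangential_shift=-0.7),
        SubunitPerturbation(axial_shift=0.5),
        SubunitPerturbation(twist_deg=3.0),
        SubunitPerturbation(radial_shift=-0.4, axial_shift=-0.3),
        SubunitPerturbation(),
    ]
    return make_ring(SyntheticRingSpec(perturbations=perts))


@pytest.fixture
def ring_and_dna():
    """Hexamer hosting a planar circular ssDNA path, clockwise from +z."""
    return ring_with_dna(
        SyntheticRingSpec(),
        SyntheticDNASpec(radius=18.0, n_nucleotides=12, angular_step=-30.0),
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


def apply_rigid(assembly, rot, trans):
    """Rigidly transform every atom of an assembly in place-copy."""
    import copy

    moved = copy.deepcopy(assembly)
    for chain in moved.chains:
        for res in chain.residues:
            for name in res.atoms:
                res.atoms[name] = rot @ res.atoms[name] + trans
    return moved
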