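"""Synthetic assemblies with known ground truth.

Every analysis stage in this package can be exercised without external
coordinates: near-C_n rings of point-cloud subunits with controlled
radial/tangential/axial/twist perturbations, circular or helical ssDNA
paths of known handedness threaded through a ring, and Hill-model
titration series with additive truncated-Gaussian noise.  All generators
are pure functions of (spec, seed), and each returns the ground truth
(construction axis, per-subunit transforms, true parameters) needed to
check downstream statistics analytically.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .binding import TitrationSeries, hill_model
from .channel import ChannelAxis
from .errors import ConfigError
from .na_path import NAPath, Nucleotide
from .structures import Assembly, Chain, Residue


def default_monomer(n_points: int = 30) -> np.ndarray:
    """The fixed pseudo-fold used as the default subunit template: a
    deterministic centered 30-point cloud of ~4 A spread.  Fixed (not
    freshly random) so test values are stable across versions."""
    rng = np.random.default_rng(20140401)
    pts = rng.normal(scale=4.0, size=(n_points, 3))
    return pts - pts.mean(axis=0)


@dataclass
class SubunitPerturbation:
    """Rigid perturbation of one subunit in its local ring frame (A, deg)."""

    radial_shift: float = 0.0
    tangential_shift: float = 0.0
    axial_shift: float = 0.0
    twist_deg: float = 0.0


@dataclass
class SyntheticRingSpec:
    """Recipe for a near-C_n ring about the +z axis through the origin.

    ``perturbations`` gives one explicit :class:`SubunitPerturbation` per
    subunit; alternatively ``gaussian_sigmas`` draws i.i.d. perturbations
    with the given standard deviations using ``seed``.
    """

    n_subunits: int = 6
    ring_radius: float = 25.0
    monomer: np.ndarray | None = None
    perturbations: list[SubunitPerturbation] | None = None
    gaussian_sigmas: SubunitPerturbation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ConfigError("a ring needs n_subunits >= 3")
        if self.ring_radius <= 0:
            raise ConfigError("ring_radius must be positive")
        if (self.perturbations is not None
                and len(self.perturbations) != self.n_subunits):
            raise ConfigError("need one perturbation per subunit")


@dataclass
class RingGroundTruth:
    """Construction axis and the exact per-subunit rigid transforms."""

    axis: ChannelAxis
    rotations: list[np.ndarray]
    translations: list[np.ndarray]
    perturbations: list[SubunitPerturbation]


def _rot_z(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_CHAIN_LETTERS = string.ascii_uppercase + string.ascii_lowercase


def make_ring(spec: SyntheticRingSpec) -> tuple[Assembly, RingGroundTruth]:
    """Place n perturbed copies of the monomer at equal angles about +z.

    With zero perturbation the assembly is exactly C_n about the
    construction axis (the +z axis through the origin).  Chains are
    lettered A, B, C, ... in counterclockwise order viewed from +z; each
    template point becomes one CA-only alanine residue numbered from 1.
    """
    monomer = (spec.monomer if spec.monomer is not None
               else default_monomer())
    monomer = np.asarray(monomer, dtype=float)
    n = spec.n_subunits
    if spec.perturbations is not None:
        perts = spec.perturbations
    elif spec.gaussian_sigmas is not None:
        rng = np.random.default_rng(spec.seed)
        sig = spec.gaussian_sigmas
        perts = [
            SubunitPerturbation(
                radial_shift=rng.normal(0, sig.radial_shift) if sig.radial_shift else 0.0,
                tangential_shift=rng.normal(0, sig.tangential_shift) if sig.tangential_shift else 0.0,
                axial_shift=rng.normal(0, sig.axial_shift) if sig.axial_shift else 0.0,
                twist_deg=rng.normal(0, sig.twist_deg) if sig.twist_deg else 0.0,
            )
            for _ in range(n)
        ]
    else:
        perts = [SubunitPerturbation() for _ in range(n)]

    chains, rotations, translations = [], [], []
    for i in range(n):
        theta = 360.0 * i / n
        base_rot = _rot_z(theta)
        pert = perts[i]
        # local frame of subunit i: radial, tangential, axial
        u_r = base_rot @ np.array([1.0, 0.0, 0.0])
        u_t = base_rot @ np.array([0.0, 1.0, 0.0])
        u_z = np.array([0.0, 0.0, 1.0])
        center = (spec.ring_radius + pert.radial_shift) * u_r \
            + pert.tangential_shift * u_t + pert.axial_shift * u_z
        rot = _rot_z(pert.twist_deg) @ base_rot
        coords = monomer @ rot.T + center
        rotations.append(rot)
        translations.append(center)
        residues = [
            Residue(number=k + 1, name="ALA", atoms={"CA": coords[k]})
            for k in range(len(monomer))
        ]
        chains.append(Chain(id=_CHAIN_LETTERS[i], polymer_kind="protein",
                            residues=residues))
    assembly = Assembly(chains=chains, name=f"synthetic_c{n}_ring")
    truth = RingGroundTruth(
        axis=ChannelAxis(direction=np.array([0.0, 0.0, 1.0]),
                         point=np.zeros(3), c_face_sign=1),
        rotations=rotations,
        translations=translations,
        perturbations=list(perts),
    )
    return assembly, truth


@dataclass
class SyntheticDNASpec:
    """Circular/helical single-stranded DNA path inside a ring.

    The sign of ``angular_step`` sets the handedness: viewed from +z,
    a negative step advances clockwise.  ``gaps`` lists residue numbers
    omitted from the model (the numbering keeps counting through them,
    as for disordered nucleotides).
    """

    radius: float = 20.0
    z_offset: float = 0.0
    n_nucleotides: int = 12
    angular_step: float = -30.0
    rise_per_nt: float = 0.0
    start_angle: float = 0.0
    gaps: frozenset[int] = field(default_factory=frozenset)
    chain_id: str = "M"

    def __post_init__(self) -> None:
        if self.n_nucleotides < 3:
            raise ConfigError("need n_nucleotides >= 3")
        if self.radius <= 0:
            raise ConfigError("radius must be positive")
        if self.angular_step == 0:
            raise ConfigError("angular_step must be nonzero")


def make_dna(spec: SyntheticDNASpec) -> NAPath:
    """Nucleotide reference points along the specified path, numbered from
    1 in construction (5'->3') order; ``gaps`` positions are skipped."""
    nucleotides = []
    for i in range(spec.n_nucleotides):
        number = i + 1
        if number in spec.gaps:
            continue
        angle = np.radians(spec.start_angle + i * spec.angular_step)
        ref = np.array([
            spec.radius * np.cos(angle),
            spec.radius * np.sin(angle),
            spec.z_offset + i * spec.rise_per_nt,
        ])
        # a short stand-in backbone so heavy-atom contact counting works
        atoms = {
            "C1'": ref,
            "P": ref + np.array([0.0, 0.0, 1.2]),
            "N1": ref * (1.0 - 1.5 / max(spec.radius, 1e-9)),
        }
        nucleotides.append(
            Nucleotide(number=number, name="DT", ref_point=ref, atoms=atoms)
        )
    numbers = [nt.number for nt in nucleotides]
    gaps = [(a + 1, b - 1) for a, b in zip(numbers, numbers[1:]) if b - a > 1]
    return NAPath(nucleotides=nucleotides, gaps=gaps, chain_id=spec.chain_id)


def dna_to_chain(path: NAPath) -> Chain:
    """Materialize a synthetic DNA path as an Assembly chain."""
    residues = [
        Residue(number=nt.number, name=nt.name, atoms=dict(nt.atoms))
        for nt in path.nucleotides
    ]
    return Chain(id=path.chain_id, polymer_kind="dna", residues=residues)


def ring_with_dna(
    ring_spec: SyntheticRingSpec, dna_spec: SyntheticDNASpec
) -> tuple[Assembly, RingGroundTruth, NAPath]:
    """A host ring with a DNA path merged into one assembly."""
    assembly, truth = make_ring(ring_spec)
    path = make_dna(dna_spec)
    assembly.chains.append(dna_to_chain(path))
    assembly.validate()
    return assembly, truth, path


def simulate_titration(
    concentrations,
    k_half: float,
    h: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TitrationSeries:
    """Forward-model titration: Hill fractions at each concentration plus
    truncated-Gaussian noise (independent on free and bound, clipped to
    [0, 1]).  Deterministic per seed."""
    conc = np.asarray(concentrations, dtype=float)
    free, bound = hill_model(conc, k_half, h)
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        free = np.clip(free + rng.normal(0, noise_sd, size=free.shape), 0, 1)
        bound = np.clip(bound + rng.normal(0, noise_sd, size=bound.shape), 0, 1)
    return TitrationSeries(
        concentrations=conc, frac_free=free, frac_bound=bound, label=label,
        sum_tolerance=max(0.2, 8 * noise_sd),
    )


#: protein concentration ladders (uM) used in the EMSA titrations
WT_SSDNA_LADDER = (1.4, 2.0, 2.7, 6.8, 13.5, 20.3, 27.0, 40.5, 54.0)
DOUBLE_MUTANT_LADDER = (54.0, 81.0, 108.0, 135.0, 162.0, 189.0, 216.0,
                        243.0, 270.0)
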