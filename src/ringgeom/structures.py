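"""Coordinate-file I/O and atom selection.

Parsing of PDB/mmCIF is delegated to :mod:`gemmi`; this module converts
the parsed hierarchy into small plain containers (:class:`Assembly`,
:class:`Chain`, :class:`Residue`) that the geometry modules consume, and
implements the selection rules used throughout the package:

* author residue numbering is authoritative,
* alternate locations resolve to the highest-occupancy conformer
  (ties broken toward altloc ``A``),
* insertion-coded residues are distinct residues ordered after their
  base number,
* multi-chain selections use the intersection of residue numbers that
  carry the requested atom in every chain, and the dropped residues are
  reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import AtomLookupError, SelectionError, StructureParseError

logger = logging.getLogger(__name__)

_PROTEIN = "protein"
_DNA = "dna"
_RNA = "rna"
_OTHER = "other"


@dataclass
class Residue:
    """One residue: author number, optional insertion code, name, atoms."""

    number: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    icode: str = ""
    het: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Chain:
    id: str
    polymer_kind: str = _OTHER
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue:
        for res in self.residues:
            if res.number == number and res.icode == icode:
                return res
        raise AtomLookupError(
            f"chain {self.id}: residue {number}{icode or ''} not present"
        )


@dataclass
class Assembly:
    """An atomic model: ordered chains of ordered residues."""

    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chain in self.chains:
            if chain.id in seen:
                raise StructureParseError(f"duplicate chain id {chain.id!r}")
            seen.add(chain.id)
            keys = [r.key for r in chain.residues]
            for a, b in zip(keys, keys[1:]):
                if b <= a:
                    raise StructureParseError(
                        f"chain {chain.id}: residue order not strictly "
                        f"increasing at {a} -> {b}"
                    )
            for res in chain.residues:
                for atom_name, xyz in res.atoms.items():
                    if not np.all(np.isfinite(xyz)):
                        raise StructureParseError(
                            f"non-finite coordinates at {chain.id}/"
                            f"{res.number}/{atom_name}"
                        )

    def chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        raise AtomLookupError(f"chain {chain_id!r} not in assembly")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def atom(self, chain_id: str, resnum: int, atom_name: str) -> np.ndarray:
        res = self.chain(chain_id).residue(resnum)
        try:
            return res.atoms[atom_name]
        except KeyError:
            raise AtomLookupError(
                f"atom {atom_name!r} absent in {chain_id}/{res.name}{resnum}"
            ) from None


@dataclass
class RingDefinition:
    """Ordered chains of one ring plus the superposition subdomain.

    ``ordered_chains`` lists subunits in ring order, counterclockwise when
    viewed from the declared C-terminal face.  ``subdomain_range`` is the
    inclusive author-numbered residue interval used for superposition
    (for MCM N-domain rings, the OB-fold C-subdomain).
    """

    ordered_chains: list[str]
    subdomain_range: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ordered_chains) < 3:
            raise SelectionError("a ring needs at least 3 chains")
        if len(set(self.ordered_chains)) != len(self.ordered_chains):
            raise SelectionError("ring chain ids must be unique")
        lo, hi = self.subdomain_range
        if hi < lo:
            raise SelectionError(f"empty subdomain range {lo}-{hi}")

    @property
    def n(self) -> int:
        return len(self.ordered_chains)


def _residue_kind(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return _OTHER
    if info.is_amino_acid():
        return _PROTEIN
    if info.is_nucleic_acid():
        # deoxy residues in the PDB chemical dictionary start with D
        return _DNA if name.strip().upper().startswith("D") else _RNA
    return _OTHER


def _chain_kind(residues: list[Residue]) -> str:
    counts: dict[str, int] = {}
    for res in residues:
        if res.het:
            continue
        kind = _residue_kind(res.name)
        counts[kind] = counts.get(kind, 0) + 1
    if not counts:
        return _OTHER
    return max(counts, key=counts.get)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the alphabetically first altloc
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def load_assembly(path: str | Path, format: str = "auto") -> Assembly:
    """Read a PDB or mmCIF file into an :class:`Assembly`.

    Heteroatom residues (ions, waters) are retained and flagged ``het``;
    they do not contribute to a chain's polymer kind.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise StructureParseError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = {
                name: np.array(
                    [(a := _pick_altloc(alts)).pos.x, a.pos.y, a.pos.z]
                )
                for name, alts in by_name.items()
            }
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    name=gres.name,
                    atoms=atoms,
                    icode=(gres.seqid.icode or "").strip(),
                    het=gres.het_flag == "H",
                )
            )
        residues.sort(key=lambda r: r.key)
        chains.append(
            Chain(id=gchain.name, polymer_kind=_chain_kind(residues),
                  residues=residues)
        )
    return Assembly(chains=chains, name=path.stem)


def _to_gemmi(assembly: Assembly) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = assembly.name or "ringgeom"
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.het else "A"
            for atom_name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_guess_element(atom_name))
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 20.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    return st


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper() if name else "X"


def write_assembly(assembly: Assembly, path: str | Path,
                   format: str = "auto") -> None:
    """Write an assembly as PDB or mmCIF (chosen from the extension if
    ``format='auto'``)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(assembly)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureParseError(f"unknown format {format!r}")


def select_coords(
    assembly: Assembly,
    ring: RingDefinition,
    atom_name: str = "CA",
) -> tuple[dict[str, np.ndarray], list[int]]:
    """Per-chain coordinate arrays for one atom type over the ring subdomain.

    Returns ``(coords, residue_numbers)`` where ``coords[chain_id]`` is an
    ``(m, 3)`` array and ``residue_numbers`` lists the ``m`` author residue
    numbers, identical (and identically ordered) for every chain: the
    intersection of residue numbers that carry ``atom_name`` in all chains.
    """
    lo, hi = ring.subdomain_range
    per_chain: dict[str, dict[int, np.ndarray]] = {}
    for cid in ring.ordered_chains:
        chain = assembly.chain(cid)
        found = {
            res.number: res.atoms[atom_name]
            for res in chain.residues
            if lo <= res.number <= hi and not res.icode
            and atom_name in res.atoms
        }
        if not found:
            raise SelectionError(
                f"chain {cid}: no {atom_name!r} atoms in residues {lo}-{hi}"
            )
        per_chain[cid] = found

    common = set.intersection(*(set(d) for d in per_chain.values()))
    if not common:
        raise SelectionError(
            f"no residue in {lo}-{hi} has {atom_name!r} in every ring chain"
        )
    union = set.union(*(set(d) for d in per_chain.values()))
    dropped = sorted(union - common)
    if dropped:
        logger.warning(
            "select_coords: dropped residues %s missing %s in >=1 chain",
            dropped, atom_name,
        )
    numbers = sorted(common)
    coords = {
        cid: np.array([per_chain[cid][num] for num in numbers])
        for cid in ring.ordered_chains
    }
    return coords, numbers


def extract_na_path(assembly: Assembly, chain_ids: list[str] | str):
    """Build a 5'->3' nucleotide path (see :mod:`ringgeom.na_path`) from
    the named nucleic-acid chains. One :class:`~ringgeom.na_path.NAPath`
    per chain is returned when several ids are given.

    The per-nucleotide reference point is C1' when modeled, else P.
    """
    from .na_path import NAPath, Nucleotide

    single = isinstance(chain_ids, str)
    ids = [chain_ids] if single else list(chain_ids)
    paths = []
    for cid in ids:
        chain = assembly.chain(cid)
        if chain.polymer_kind not in (_DNA, _RNA):
            raise SelectionError(
                f"chain {cid} is {chain.polymer_kind}, not nucleic acid"
            )
        nucleotides = []
        for res in chain.residues:
            if res.het:
                continue
            ref = res.atoms.get("C1'", res.atoms.get("P"))
            if ref is None:
                raise AtomLookupError(
                    f"nucleotide {cid}/{res.name}{res.number} has neither "
                    "C1' nor P"
                )
            nucleotides.append(
                Nucleotide(number=res.number, name=res.name,
                           ref_point=np.asarray(ref, dtype=float),
                           atoms=dict(res.atoms))
            )
        numbers = [nt.number for nt in nucleotides]
        gaps = [
            (a + 1, b - 1)
            for a, b in zip(numbers, numbers[1:])
            if b - a > 1
        ]
        paths.append(NAPath(nucleotides=nucleotides, gaps=gaps, chain_id=cid))
    return paths[0] if single else paths
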