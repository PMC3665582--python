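"""Typed coordinate model of a protein structure and the geometric
primitives every analysis relies on: PDB reading, backbone/sidechain
torsions, relative solvent accessibility and in-silico mutant sidechain
construction.

Residues are identified by (chain_id, seq_num, insert_code) exactly as
numbered in the source file; no renumbering is performed.  Alternate
locations are resolved to the highest-occupancy conformer, waters are
excluded, and only the first model of multi-model files is read.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from . import sasa, templates
from .geometry import dihedral
from .params import ONE_TO_THREE, STANDARD_AA3, THREE_TO_ONE, element_of, vdw_entry

__all__ = [
    "Atom", "Residue", "Structure", "MutationSpec", "Dihedrals",
    "AccessResult", "ResidueID",
    "read_pdb", "backbone_dihedrals", "sidechain_chis",
    "relative_accessibility", "build_mutant_sidechain",
    "StructureError", "ResidueNotFoundError", "NativeMismatchError",
    "MissingAtomsError",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")
WATER_NAMES = {"HOH", "WAT", "DOD"}

ResidueID = tuple  # (chain_id, seq_num, insert_code)


class StructureError(Exception):
    """Base error for structure handling."""


class ResidueNotFoundError(StructureError):
    pass


class NativeMismatchError(StructureError):
    """The native residue stated in a mutation does not match the file."""


class MissingAtomsError(StructureError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_het: bool = False
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insert_code: str
    aa_type: str            # 3-letter code (or het name)
    atoms: list = field(default_factory=list)

    @property
    def id(self) -> ResidueID:
        return (self.chain_id, self.seq_num, self.insert_code)

    @property
    def aa1(self) -> Optional[str]:
        return THREE_TO_ONE.get(self.aa_type)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    def sidechain_atoms(self) -> list:
        return [a for a in self.atoms if a.name not in BACKBONE_NAMES]

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def __repr__(self):  # compact, used in report details
        ins = self.insert_code or ""
        return f"{self.aa_type} {self.chain_id}{self.seq_num}{ins}"


@dataclass
class Structure:
    id: str
    chains: dict = field(default_factory=dict)       # chain_id -> [Residue]
    het_groups: list = field(default_factory=list)   # non-water ligands
    waters_excluded: bool = True
    resolution: Optional[float] = None

    def __post_init__(self):
        self._index = {}
        for chain_id, residues in self.chains.items():
            for pos, res in enumerate(residues):
                self._index[(chain_id, res.seq_num, res.insert_code)] = (chain_id, pos)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def get_residue(self, residue_id) -> Residue:
        rid = _normalise_rid(residue_id)
        if rid not in self._index:
            raise ResidueNotFoundError(
                f"residue {rid} not found in structure {self.id!r}")
        chain_id, pos = self._index[rid]
        return self.chains[chain_id][pos]

    def neighbour(self, residue_id, offset: int) -> Optional[Residue]:
        """Residue `offset` positions away in file order on the same chain."""
        rid = _normalise_rid(residue_id)
        if rid not in self._index:
            raise ResidueNotFoundError(f"residue {rid} not found")
        chain_id, pos = self._index[rid]
        new = pos + offset
        chain = self.chains[chain_id]
        if 0 <= new < len(chain):
            return chain[new]
        return None


def _normalise_rid(residue_id) -> ResidueID:
    if len(residue_id) == 2:
        chain, seq = residue_id
        return (str(chain), int(seq), "")
    chain, seq, ins = residue_id
    return (str(chain), int(seq), str(ins or "").strip())


@dataclass
class MutationSpec:
    """One amino-acid substitution mapped to a structure position.

    `mutation_key` identifies the mutation independently of the structure
    (e.g. accession:position:mutant) and is the grouping handle that keeps
    the same mutation out of both train and test folds.
    """
    structure_ref: str
    chain_id: str
    seq_num: int
    native_aa: str
    mutant_aa: str
    insert_code: str = ""
    mutation_key: str = ""

    def __post_init__(self):
        self.native_aa = self.native_aa.upper()
        self.mutant_aa = self.mutant_aa.upper()
        for aa in (self.native_aa, self.mutant_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown amino acid code {aa!r}")
        if self.native_aa == self.mutant_aa:
            raise ValueError("native and mutant amino acid are identical")
        if not self.mutation_key:
            self.mutation_key = (
                f"{self.structure_ref}:{self.chain_id}{self.seq_num}"
                f"{self.insert_code}:{self.mutant_aa}")

    @property
    def residue_id(self) -> ResidueID:
        return (self.chain_id, self.seq_num, self.insert_code)

    def check_against(self, structure: Structure) -> Residue:
        res = structure.get_residue(self.residue_id)
        if res.aa1 != self.native_aa:
            raise NativeMismatchError(
                f"native {self.native_aa} does not match {res!r}")
        return res


@dataclass
class Dihedrals:
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]     # peptide-bond torsion preceding the residue
    chi: list = field(default_factory=list)


def read_pdb(path, structure_id: Optional[str] = None) -> Structure:
    """Parse a PDB file into a Structure.

    MODEL 1 only; waters excluded; alternate locations resolved to the
    highest-occupancy conformer (ties keep the first-listed, i.e. 'A').
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio = parser.get_structure(structure_id or "structure", str(path))
        except Exception as exc:
            raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise StructureError(f"no coordinate model in {path}")
    model = models[0]

    chains: dict = {}
    het_groups: list = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            hetflag, seq, icode = res.id
            resname = res.get_resname().strip()
            if hetflag == "W" or resname in WATER_NAMES:
                continue
            atoms = []
            for atom in res:  # disordered atoms yield the selected conformer
                atoms.append(Atom(
                    name=atom.get_name().strip(),
                    element=(atom.element or element_of(atom.get_name())).strip().upper()
                    or element_of(atom.get_name()),
                    coords=atom.get_coord(),
                    is_het=hetflag != " ",
                    occupancy=atom.get_occupancy() if atom.get_occupancy() is not None else 1.0,
                    bfactor=atom.get_bfactor() if atom.get_bfactor() is not None else 0.0,
                ))
            if not atoms:
                continue
            n_atoms += len(atoms)
            residue = Residue(chain.id.strip() or chain.id, seq,
                              icode.strip(), resname, atoms)
            if hetflag == " ":
                chains.setdefault(residue.chain_id, []).append(residue)
            else:
                het_groups.append(residue)
    if n_atoms == 0:
        raise StructureError(f"no ATOM/HETATM records in {path}")

    header = getattr(bio, "header", {}) or {}
    resolution = header.get("resolution")
    sid = structure_id or str(path)
    return Structure(id=sid, chains=chains, het_groups=het_groups,
                     resolution=resolution)


def _coords(res: Residue, name: str) -> Optional[np.ndarray]:
    a = res.atom(name)
    return None if a is None else a.coords


def backbone_dihedrals(structure: Structure, residue_id) -> Dihedrals:
    """phi/psi/omega and sidechain chi torsions of a residue, degrees.

    Angles whose defining atoms are missing (chain termini, incomplete
    residues) are None rather than raising.
    """
    res = structure.get_residue(residue_id)
    prev = structure.neighbour(residue_id, -1)
    nxt = structure.neighbour(residue_id, +1)

    n, ca, c = (_coords(res, x) for x in ("N", "CA", "C"))
    phi = psi = omega = None

    def _defined(*pts):
        return all(p is not None for p in pts)

    if prev is not None:
        c_prev, ca_prev = _coords(prev, "C"), _coords(prev, "CA")
        if _defined(c_prev, n, ca, c):
            phi = dihedral(c_prev, n, ca, c)
        if _defined(ca_prev, c_prev, n, ca):
            omega = dihedral(ca_prev, c_prev, n, ca)
    if nxt is not None:
        n_next = _coords(nxt, "N")
        if _defined(n, ca, c, n_next):
            psi = dihedral(n, ca, c, n_next)
    return Dihedrals(phi=phi, psi=psi, omega=omega, chi=sidechain_chis(res))


def sidechain_chis(res: Residue) -> list:
    """Chi torsions (degrees) for the residue; None entries where atoms
    are missing or the residue type defines fewer torsions."""
    defs = templates.CHI_ATOMS.get(res.aa_type, [])
    chis = []
    for quad in defs:
        pts = [_coords(res, nm) for nm in quad]
        chis.append(None if any(p is None for p in pts) else dihedral(*pts))
    return chis


@dataclass
class AccessResult:
    relative: float   # in [0, 1]
    absolute: float   # Angstrom^2
    partial: bool     # computed on an incomplete atom set


def _atom_pool(structure: Structure, chain_only: Optional[str]) -> list:
    pool = []
    for chain_id, residues in structure.chains.items():
        if chain_only is not None and chain_id != chain_only:
            continue
        for res in residues:
            pool.extend((res.id, a) for a in res.atoms)
    if chain_only is None:
        for het in structure.het_groups:
            pool.extend((het.id, a) for a in het.atoms)
    return pool


def relative_accessibility(structure: Structure, residue_id,
                           context: str = "full_complex") -> AccessResult:
    """Residue SASA relative to its extended Gly-X-Gly reference.

    context 'isolated_chain' computes accessibility with only the
    residue's own chain present; 'full_complex' uses every chain plus
    non-water het groups as occluders.
    """
    if context not in ("isolated_chain", "full_complex"):
        raise ValueError(f"unknown context {context!r}")
    res = structure.get_residue(residue_id)
    rid = res.id
    chain_only = rid[0] if context == "isolated_chain" else None
    pool = _atom_pool(structure, chain_only)
    coords = np.array([a.coords for _, a in pool])
    radii = np.array([vdw_entry(a.element).vdw_radius for _, a in pool])
    areas = sasa.shrake_rupley(coords, radii)
    mask = np.array([owner == rid for owner, _ in pool])
    absolute = float(areas[mask].sum())

    partial = False
    if res.aa_type in STANDARD_AA3:
        expected = len(templates.residue_template(res.aa_type)[0])
        partial = len(res.atoms) < expected
        ref = sasa.gxg_reference(res.aa1)
    else:
        partial = True
        ref = sasa.gxg_reference("A")
    relative = min(absolute / ref, 1.0) if ref > 0 else 0.0
    return AccessResult(relative=relative, absolute=absolute, partial=partial)


def build_mutant_sidechain(structure: Structure, residue_id,
                           mutant_aa: str) -> Residue:
    """Graft the mutant sidechain onto the native backbone.

    Chi torsions shared with the native sidechain are inherited; torsions
    with no native counterpart default to 180 deg (extended).  An X->X
    "mutation" returns the native residue unchanged.
    """
    res = structure.get_residue(residue_id)
    mutant_aa = mutant_aa.upper()
    if mutant_aa not in ONE_TO_THREE:
        raise ValueError(f"unknown amino acid code {mutant_aa!r}")
    mutant3 = ONE_TO_THREE[mutant_aa]
    if res.aa_type == mutant3:
        return copy.deepcopy(res)
    if not res.has_backbone:
        raise MissingAtomsError(f"{res!r} lacks backbone atoms N/CA/C")

    native_chis = sidechain_chis(res)
    n_chi = len(templates.CHI_ATOMS[mutant3])
    targets = []
    for k in range(n_chi):
        inherited = native_chis[k] if k < len(native_chis) else None
        targets.append(inherited if inherited is not None else 180.0)

    n, ca, c = (res.atom(x).coords for x in ("N", "CA", "C"))
    side = templates.attach_sidechain(mutant3, n, ca, c, targets)

    atoms = [copy.deepcopy(res.atom(nm)) for nm in BACKBONE_NAMES
             if res.atom(nm) is not None]
    for nm in templates.sidechain_atom_names(mutant3):
        atoms.append(Atom(name=nm, element=element_of(nm), coords=side[nm]))
    return Residue(res.chain_id, res.seq_num, res.insert_code, mutant3, atoms)
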