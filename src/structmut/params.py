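"""Packaged parameter tables and amino-acid lookup helpers.

Tables ship as TSV inside ``structmut/data`` and can be overridden by
passing an alternative file path to the loaders.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STANDARD_AA3",
    "HYDROPHOBIC",
    "HYDROPHILIC",
    "NEUTRAL",
    "CHARGE",
    "VdwEntry",
    "load_vdw_table",
    "vdw_entry",
    "TorsionParams",
    "load_torsion_table",
    "load_hydropathy",
    "load_hbond_atoms",
    "load_residue_volumes",
    "element_of",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)

# Polarity classes used by the corephilic / surfacephobic rules.
HYDROPHOBIC = frozenset("AVLIMFWC")
HYDROPHILIC = frozenset("DEKRNQHST")
NEUTRAL = frozenset("GPY")

# Formal sidechain charge at physiological pH.
CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}


def _data_path(name: str) -> Path:
    return Path(resources.files("structmut").joinpath("data", name))


def _read_tsv(path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass(frozen=True)
class VdwEntry:
    element: str
    rmin_half: float   # Angstrom
    epsilon: float     # kcal/mol
    vdw_radius: float  # Angstrom, hard-sphere radius for the overlap count


@functools.lru_cache(maxsize=8)
def load_vdw_table(path=None) -> dict:
    """Element -> VdwEntry; '*' row is the fallback for unknown elements."""
    path = path or _data_path("vdw_params.tsv")
    table = {}
    for el, rmin_half, eps, rad in _read_tsv(path):
        table[el.upper()] = VdwEntry(el.upper(), float(rmin_half), float(eps), float(rad))
    return table


def vdw_entry(element: str, table=None) -> VdwEntry:
    table = table or load_vdw_table()
    return table.get(element.upper(), table["*"])


@dataclass(frozen=True)
class TorsionParams:
    torsion_class: str
    k: float      # kcal/mol
    n: int        # periodicity
    phase: float  # degrees

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("torsion k must be >= 0")
        if self.n not in (1, 2, 3, 4, 6):
            raise ValueError(f"unsupported torsion periodicity {self.n}")


@functools.lru_cache(maxsize=8)
def load_torsion_table(path=None) -> dict:
    path = path or _data_path("torsion_params.tsv")
    table = {}
    for cls, k, n, phase in _read_tsv(path):
        table[cls] = TorsionParams(cls, float(k), int(n), float(phase))
    return table


@functools.lru_cache(maxsize=8)
def load_hydropathy(path=None) -> dict:
    """aa(1-letter) -> (kd_score, polarity_class)."""
    path = path or _data_path("hydropathy.tsv")
    return {aa: (float(kd), cls) for aa, kd, cls in _read_tsv(path)}


@functools.lru_cache(maxsize=8)
def load_hbond_atoms(path=None) -> dict:
    """residue(3-letter) -> {atom_name: (role, group)}."""
    path = path or _data_path("hbond_atoms.tsv")
    table: dict = {}
    for res, atom, role, group in _read_tsv(path):
        table.setdefault(res, {})[atom] = (role, group)
    return table


@functools.lru_cache(maxsize=8)
def load_residue_volumes(path=None) -> dict:
    path = path or _data_path("residue_volume.tsv")
    return {aa: float(v) for aa, v in _read_tsv(path)}


def element_of(atom_name: str) -> str:
    """Infer the chemical element from a PDB heavy-atom name.

    Strips leading digits; two-letter elements common in protein/het
    groups (FE, ZN, MG, CL, BR) are recognised, otherwise the first
    letter wins (CA the atom name is carbon, not calcium — PDB protein
    convention).
    """
    name = atom_name.strip().lstrip("0123456789")
    upper = name.upper()
    if upper in ("FE", "ZN", "MG", "BR", "CL", "NA", "MN", "CU"):
        return upper
    return upper[0] if upper else "C"
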