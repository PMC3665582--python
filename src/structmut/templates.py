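"""Ideal residue geometry and sidechain construction.

Heavy-atom templates for the twenty standard residues come from the
chemical component dictionary bundled with biotite.  Sidechains are
grafted onto an existing backbone by superimposing the template N/CA/C
frame and then driving each chi torsion to a requested value.

Also provides an internal-coordinate peptide builder used to construct
idealised chains (helices, extended reference tripeptides, engineered
fixtures).
"""
from __future__ import annotations

import functools

import numpy as np
import biotite.structure.info as struc_info

from .geometry import dihedral, kabsch, place_atom, rotate_about_axis
from .params import ONE_TO_THREE, STANDARD_AA3

__all__ = [
    "CHI_ATOMS",
    "PLANAR_CHIS",
    "residue_template",
    "sidechain_atom_names",
    "attach_sidechain",
    "build_peptide",
]

# Atom quadruples defining chi1..chi_k per residue (IUPAC).
CHI_ATOMS = {
    "ALA": [],
    "GLY": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# (residue, chi index 1-based) pairs whose torsion rotates a planar group.
PLANAR_CHIS = {
    ("PHE", 2), ("TYR", 2), ("TRP", 2), ("HIS", 2),
    ("ASN", 2), ("ASP", 2), ("GLN", 3), ("GLU", 3), ("ARG", 4),
}

BACKBONE = ("N", "CA", "C", "O")

# Ideal backbone internal coordinates (Engh-Huber-style means).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


@functools.lru_cache(maxsize=32)
def residue_template(aa3: str):
    """Heavy-atom ideal coordinates and bonds for a standard residue.

    Returns (names, coords, adjacency) where adjacency maps an atom name
    to the set of covalently bonded atom names.  OXT and hydrogens are
    dropped.
    """
    aa3 = aa3.upper()
    if aa3 not in STANDARD_AA3:
        raise ValueError(f"not a standard amino acid: {aa3!r}")
    res = struc_info.residue(aa3)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    idx = np.flatnonzero(keep)
    names = [str(n) for n in res.atom_name[idx]]
    coords = res.coord[idx].astype(float)
    pos = {orig: new for new, orig in enumerate(idx)}
    adjacency: dict = {n: set() for n in names}
    for i, j, _ in res.bonds.as_array():
        if i in pos and j in pos:
            a, b = names[pos[i]], names[pos[j]]
            adjacency[a].add(b)
            adjacency[b].add(a)
    return names, coords, adjacency


def sidechain_atom_names(aa3: str) -> list[str]:
    """Heavy sidechain atom names (CB onwards) in template order."""
    names, _, _ = residue_template(aa3)
    return [n for n in names if n not in BACKBONE]


def _distal_atoms(adjacency, axis_a: str, axis_b: str) -> set[str]:
    """Atoms on the axis_b side of the rotatable bond axis_a-axis_b."""
    seen = {axis_a, axis_b}
    stack = [axis_b]
    out = set()
    while stack:
        cur = stack.pop()
        for nb in adjacency[cur]:
            if nb not in seen:
                seen.add(nb)
                out.add(nb)
                stack.append(nb)
    return out


def attach_sidechain(aa3: str, n, ca, c, chis=None) -> dict:
    """Build the heavy sidechain of `aa3` on the backbone frame (n, ca, c).

    `chis` is a sequence of target chi values in degrees; entries may be
    None (keep the template value; callers use 180 for 'extended' when a
    deterministic default is wanted).  Proline's ring torsions are kept at
    template values regardless, since driving one torsion of a closed
    ring would break closure.

    Returns {atom_name: coords} for sidechain atoms (CB onwards); Gly
    gives an empty dict.
    """
    aa3 = aa3.upper()
    names, coords, adjacency = residue_template(aa3)
    coords = coords.copy()
    index = {nm: i for i, nm in enumerate(names)}
    R, t = kabsch(
        np.array([coords[index["N"]], coords[index["CA"]], coords[index["C"]]]),
        np.array([n, ca, c], dtype=float),
    )
    coords = coords @ R.T + t
    # pin the backbone frame to the real atoms so chi torsions are
    # measured and driven against the actual backbone, not the
    # superposed template's residual
    for nm, xyz in (("N", n), ("CA", ca), ("C", c)):
        coords[index[nm]] = np.asarray(xyz, float)

    if aa3 != "PRO" and chis:
        for k, target in enumerate(chis):
            if target is None or k >= len(CHI_ATOMS[aa3]):
                continue
            a, b, cdef, d = CHI_ATOMS[aa3][k]
            current = dihedral(*(coords[index[x]] for x in (a, b, cdef, d)))
            delta = target - current
            moving = [index[x] for x in _distal_atoms(adjacency, b, cdef)
                      if x not in BACKBONE]
            if not moving:
                continue
            axis = coords[index[cdef]] - coords[index[b]]
            coords[moving] = rotate_about_axis(
                coords[moving], coords[index[b]], axis, delta
            )
    return {nm: coords[index[nm]] for nm in names if nm not in BACKBONE}


def build_peptide(sequence: str, phi=-57.0, psi=-47.0, omega=180.0, chis=None):
    """Construct an idealised peptide from one-letter `sequence`.

    phi/psi/omega may be scalars or per-residue sequences; `chis` an
    optional per-residue list of chi targets (None -> template values).
    Returns a list of (aa3, {atom_name: xyz}) in chain order.
    """
    nres = len(sequence)
    if nres == 0:
        raise ValueError("empty sequence")
    for aa in sequence:
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {aa!r}")

    def per_res(x):
        if np.ndim(x) == 0:
            return [float(x)] * nres
        x = list(x)
        if len(x) != nres:
            raise ValueError("angle list length does not match sequence")
        return [float(v) for v in x]

    phis, psis, omegas = per_res(phi), per_res(psi), per_res(omega)

    bb = np.zeros((nres, 3, 3))  # N, CA, C per residue
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    bb[0, 2] = bb[0, 1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, nres):
        bb[i, 0] = place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                              _B_C_N, _A_CA_C_N, psis[i - 1])
        bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                              _B_N_CA, _A_C_N_CA, omegas[i])
        bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                              _B_CA_C, _A_N_CA_C, phis[i])

    residues = []
    for i, aa in enumerate(sequence):
        aa3 = ONE_TO_THREE[aa]
        n, ca, c = bb[i]
        atoms = {"N": n, "CA": ca, "C": c}
        # carbonyl O is anti-periplanar to the following N around CA-C
        atoms["O"] = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        res_chis = None
        if chis is not None and chis[i] is not None:
            res_chis = chis[i]
        atoms.update(attach_sidechain(aa3, n, ca, c, res_chis))
        residues.append((aa3, atoms))
    return residues
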