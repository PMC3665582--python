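"""Synthetic test-data generators.

Minimal, legal PDB files with engineered geometry (helices, clash
scenes, hydrogen bonds, disulphides, hollow shells, chain interfaces),
wrapped-Gaussian phi/psi samples for building backbone-torsion maps at
desk scale, and labelled 47-feature datasets with mutation-to-chain
multiplicity for exercising the cross-validation protocol.

Everything is deterministic under a fixed seed, and every generated
PDB file re-parses losslessly through the structure model.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import templates
from .geometry import wrap_angle
from .params import ONE_TO_THREE, element_of
from .predictor import FEATURE_NAMES

__all__ = [
    "write_pdb", "make_helix", "make_clash_fixture", "make_hbond_fixture",
    "make_ss_fixture", "make_void_fixture", "make_interface_fixture",
    "synth_dihedral_sample", "synth_mutation_dataset", "DEFAULT_BASINS",
]

VDW_CC = 3.4  # C-C hard-sphere contact distance used by clash fixtures


def _atom_line(serial, name, resname, chain, seq, xyz, element, het=False):
    record = "HETATM" if het else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"{record}{serial:5d} {name_field} {resname:>3s} {chain:1s}"
            f"{seq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_pdb(residues, path, het_atoms=()):
    """Write residues [(chain, seq, aa3, {atom: xyz})] and optional
    HETATM records [(name, resname, chain, seq, xyz)] as a minimal PDB
    file (ATOM/HETATM/TER/END only)."""
    lines = []
    serial = 1
    prev_chain = None
    for chain, seq, aa3, atoms in residues:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        order = templates.residue_template(aa3)[0] if aa3 in templates.CHI_ATOMS \
            else sorted(atoms)
        for name in order:
            if name not in atoms:
                continue
            lines.append(_atom_line(serial, name, aa3, chain, seq,
                                    atoms[name], element_of(name)))
            serial += 1
        for name in atoms:
            if name not in order:
                lines.append(_atom_line(serial, name, aa3, chain, seq,
                                        atoms[name], element_of(name)))
                serial += 1
    if residues:
        lines.append("TER")
    for name, resname, chain, seq, xyz in het_atoms:
        lines.append(_atom_line(serial, name, resname, chain, seq, xyz,
                                element_of(name), het=True))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def make_helix(n_residues: int, path, sequence=None,
               phi=-57.0, psi=-47.0, chain_id="A"):
    """Ideal alpha-helix PDB file (full backbone + sidechains)."""
    sequence = sequence or "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    built = templates.build_peptide(sequence, phi=phi, psi=psi)
    residues = [(chain_id, i + 1, aa3, atoms)
                for i, (aa3, atoms) in enumerate(built)]
    return write_pdb(residues, path)


def make_clash_fixture(overlap_depths, path, mutant_aa="I"):
    """A lone alanine plus carbon 'ligand' atoms placed to overlap the
    in-silico mutant sidechain by the requested depths.

    Each depth d puts one environment atom at (3.4 - d) Angstrom from a
    mutant sidechain atom, along the outward direction, so the legacy
    rule counts exactly len(overlap_depths) overlaps.
    """
    (aa3, atoms), = templates.build_peptide("A")
    n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
    mut3 = ONE_TO_THREE[mutant_aa]
    n_chi = len(templates.CHI_ATOMS[mut3])
    side = templates.attach_sidechain(mut3, n, ca, c, [180.0] * n_chi)
    if not side:
        raise ValueError("mutant must have a heavy sidechain")
    # aim every environment atom at the most distal sidechain atom, on a
    # narrow outward cone, so each overlaps exactly that atom and stays
    # clear of the rest of the sidechain
    target_name = max(side, key=lambda nm: np.linalg.norm(side[nm] - ca))
    target = side[target_name]
    axis = (target - ca) / np.linalg.norm(target - ca)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    perp2 = np.cross(axis, perp)

    het = []
    tilt = np.radians(25.0)
    for i, depth in enumerate(overlap_depths):
        az = 2.0 * np.pi * i / max(len(overlap_depths), 1)
        direction = (np.cos(tilt) * axis
                     + np.sin(tilt) * (np.cos(az) * perp + np.sin(az) * perp2))
        pos = target + (VDW_CC - depth) * direction
        het.append(("C1", "LIG", "L", 100 + i, pos))
    write_pdb([("A", 1, "ALA", atoms)], path, het_atoms=het)
    return {"path": Path(path), "chain": "A", "seq_num": 1,
            "native": "A", "mutant": mutant_aa,
            "legacy_count": len(overlap_depths)}


def make_hbond_fixture(path, distance=2.9):
    """Serine whose OG hydrogen-bonds a backbone carbonyl O on another
    chain at the given donor-acceptor distance."""
    (aa3, ser), = templates.build_peptide("S", chis=[[180.0]])
    og, cb = ser["OG"], ser["CB"]
    d = (og - cb) / np.linalg.norm(og - cb)
    p = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(d, [0.0, 1.0, 0.0])
    p = p / np.linalg.norm(p)
    o_pos = og + distance * d
    # acceptor's covalent neighbour (carbonyl C) at 110 deg from the bond axis
    c_dir = np.cos(np.radians(110.0)) * (-d) + np.sin(np.radians(110.0)) * p
    c_pos = o_pos + 1.23 * c_dir
    ca_pos = c_pos + 1.52 * d
    n_pos = ca_pos + 1.46 * p
    gly = {"N": n_pos, "CA": ca_pos, "C": c_pos, "O": o_pos}
    write_pdb([("A", 1, "SER", ser), ("B", 1, "GLY", gly)], path)
    return {"path": Path(path), "chain": "A", "seq_num": 1, "native": "S",
            "distance": distance}


def make_ss_fixture(path, sg_distance=2.05):
    """Two cysteines whose SG atoms sit `sg_distance` apart (a
    disulphide), backbones pointing away from each other."""
    (aa3, cys1), = templates.build_peptide("C", chis=[[180.0]])
    sg, cb = cys1["SG"], cys1["CB"]
    u = (sg - cb) / np.linalg.norm(sg - cb)
    w = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(u, [0.0, 1.0, 0.0])
    w = w / np.linalg.norm(w)
    mid = sg + (sg_distance / 2.0) * u
    from .geometry import rotate_about_axis
    names = list(cys1)
    coords = rotate_about_axis(np.array([cys1[nm] for nm in names]),
                               mid, w, 180.0)
    cys2 = dict(zip(names, coords))
    write_pdb([("A", 1, "CYS", cys1), ("A", 10, "CYS", cys2)], path)
    return {"path": Path(path), "chain": "A", "seq_num": 1, "native": "C",
            "sg_distance": sg_distance}


def _fibonacci_shell(radius: float, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)), 24)
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return radius * np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
         np.cos(phi)))


def make_void_fixture(path, inner_radius=5.0, solid=False, atom_radius=1.7,
                      spacing=1.3):
    """Hollow (or solid) carbon shell with an alanine embedded in the
    wall, its CB facing the cavity.

    For the hollow case the cavity radius is `inner_radius` (atom centres
    sit at inner_radius + atom_radius, double-walled so the 1.4 A probe
    cannot leak in); expected cavity volume is 4/3 pi r^3.
    """
    if solid:
        pts = []
        ax = np.arange(-6.0, 6.0 + 1e-9, 1.8)
        for x in ax:
            for y in ax:
                for z in ax:
                    if x * x + y * y + z * z <= 36.0:
                        pts.append((x, y, z))
        pts = np.array(pts)
        r_wall = 6.0
    else:
        r1 = inner_radius + atom_radius
        pts = np.vstack([_fibonacci_shell(r1, spacing),
                         _fibonacci_shell(r1 + 1.4, spacing)])
        r_wall = r1

    v = np.array([0.0, 0.0, 1.0])
    cb = r_wall * v
    ca = cb + 1.53 * v
    n = ca + 1.46 * np.array([0.94, 0.0, 0.34])
    c = ca + 1.53 * np.array([-0.94, 0.0, 0.34])
    o = c + 1.23 * np.array([-0.6, 0.6, 0.53])
    ala = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}

    # drop wall atoms colliding with the embedded residue
    keep = np.linalg.norm(pts - cb, axis=1) > 1.0
    for bb in (ca, n, c, o):
        keep &= np.linalg.norm(pts - bb, axis=1) > 1.6
    pts = pts[keep]
    # collar sealing the concave corner where the residue column meets
    # the wall, so no spurious crevice is counted
    az = np.linspace(0.0, 2.0 * np.pi, 9)[:-1]
    collar = np.column_stack((2.2 * np.cos(az), 2.2 * np.sin(az),
                              np.full(8, r_wall + 0.3)))
    pts = np.vstack([pts, collar])

    residues = [("A", 1, "ALA", ala)]
    residues += [("X", i + 1, "GLY", {"CA": p}) for i, p in enumerate(pts)]
    write_pdb(residues, path)
    expected = 0.0 if solid else 4.0 / 3.0 * np.pi * inner_radius ** 3
    return {"path": Path(path), "chain": "A", "seq_num": 1, "native": "A",
            "expected_volume": expected}


def make_cage_fixture(path, cage_radius=5.0, spacing=1.4,
                      countercharge_distance=None):
    """An alanine fully enclosed by a spherical carbon cage (relative
    accessibility ~ 0).

    With `countercharge_distance` set, an aspartate is placed inside the
    cage with its OD1 at that distance from where a grafted lysine NZ
    would sit, for exercising the buried-charge salt-bridge rule.
    """
    (aa3, ala), = templates.build_peptide("A")
    residues = [("A", 1, "ALA", ala)]
    if countercharge_distance is not None:
        n_chi = len(templates.CHI_ATOMS["LYS"])
        lys = templates.attach_sidechain(
            "LYS", ala["N"], ala["CA"], ala["C"], [180.0] * n_chi)
        nz = lys["NZ"]
        u = nz - ala["CA"]
        u = u / np.linalg.norm(u)
        (_, asp), = templates.build_peptide("D")
        shift = (nz + countercharge_distance * u) - asp["OD1"]
        asp = {nm: xyz + shift for nm, xyz in asp.items()}
        residues.append(("A", 5, "ASP", asp))
    centre = ala["CA"]
    cage = np.vstack([_fibonacci_shell(cage_radius, spacing),
                      _fibonacci_shell(cage_radius + 1.5, spacing)]) + centre
    keep = np.ones(len(cage), bool)
    for _, _, _, atoms in residues:
        for xyz in atoms.values():
            keep &= np.linalg.norm(cage - xyz, axis=1) > 1.2
    cage = cage[keep]
    residues += [("X", i + 1, "GLY", {"CA": p}) for i, p in enumerate(cage)]
    write_pdb(residues, path)
    return {"path": Path(path), "chain": "A", "seq_num": 1, "native": "A"}


def make_interface_fixture(path, n_residues=8, separation=8.5):
    """Two parallel poly-alanine helices in contact; returns the residue
    of chain A most buried by chain B."""
    built = templates.build_peptide("A" * n_residues, phi=-57.0, psi=-47.0)
    residues = [("A", i + 1, aa3, atoms) for i, (aa3, atoms) in enumerate(built)]
    coords_a = np.vstack([np.array(list(atoms.values()))
                          for _, atoms in built])
    axis_dir = coords_a[-1] - coords_a[0]
    axis_dir /= np.linalg.norm(axis_dir)
    offset_dir = np.cross(axis_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(offset_dir) < 0.5:
        offset_dir = np.cross(axis_dir, [0.0, 1.0, 0.0])
    offset_dir /= np.linalg.norm(offset_dir)
    offset = separation * offset_dir
    for i, (aa3, atoms) in enumerate(built):
        shifted = {nm: xyz + offset for nm, xyz in atoms.items()}
        residues.append(("B", i + 1, aa3, shifted))
    write_pdb(residues, path)

    b_coords = coords_a + offset
    target, best = 1, np.inf
    for i, (_, atoms) in enumerate(built):
        d = min(np.linalg.norm(b_coords - atoms["CB"], axis=1).min(),
                np.linalg.norm(b_coords - atoms["CA"], axis=1).min())
        if d < best:
            best, target = d, i + 1
    return {"path": Path(path), "chain": "A", "seq_num": target,
            "native": "A"}


# ------------------------------------------------------- synthetic samples

DEFAULT_BASINS = {
    "other": [(-63.0, -43.0, 10.0, 0.5), (-120.0, 130.0, 15.0, 0.5)],
    "glycine": [(-63.0, -43.0, 12.0, 0.30), (-120.0, 130.0, 15.0, 0.25),
                (63.0, 43.0, 12.0, 0.30), (85.0, -170.0, 15.0, 0.15)],
    "proline": [(-65.0, -35.0, 8.0, 0.5), (-65.0, 145.0, 8.0, 0.5)],
}


def synth_dihedral_sample(n: int, basin_spec=None, seed: int = 0):
    """Draw `n` (phi, psi) observations per residue class from wrapped
    Gaussian-mixture basins.

    basin_spec: {class: [(mean_phi, mean_psi, sigma, weight), ...]};
    defaults emulate helix/sheet basins, with the mirrored left-handed
    region for glycine and the clamped phi of proline.
    """
    basins = basin_spec or DEFAULT_BASINS
    rng = np.random.default_rng(seed)
    observations = []
    for cls, spec in basins.items():
        weights = np.array([w for _, _, _, w in spec], float)
        weights = weights / weights.sum()
        choice = rng.choice(len(spec), size=n, p=weights)
        for b, (mphi, mpsi, sigma, _) in enumerate(spec):
            m = int(np.count_nonzero(choice == b))
            if m == 0:
                continue
            phis = wrap_angle(rng.normal(mphi, sigma, m))
            psis = wrap_angle(rng.normal(mpsi, sigma, m))
            observations.extend(
                (float(a), float(b2), cls) for a, b2 in zip(phis, psis))
    order = rng.permutation(len(observations))
    return [observations[i] for i in order]


# informative features shifted between classes in the synthetic dataset
INFORMATIVE = ("clash_total_energy", "clash_lj_energy", "rama_mutant_energy",
               "rama_delta_energy", "void_volume", "hbonds_lost",
               "interface_dsasa", "conservation", "hydropathy_delta",
               "volume_delta", "charge_delta", "rel_access")

# feature pairs whose within-class correlation carries class signal
# (mimicking conjunctive effects such as burial x hydrophilicity): the
# pair is correlated in deleterious mutations and anti-correlated in
# neutral ones, with no marginal mean difference
INTERACTING = (("hydropathy_native", "countercharge_distance"),
               ("volume_native", "clash_torsion_energy"),
               ("hbonds_native", "omega"))


def synth_mutation_dataset(n_keys: int, chains_per_key: int = 1,
                           effect_size: float = 1.0, seed: int = 0,
                           pd_fraction: float = 0.5,
                           jitter: float = 0.1) -> pd.DataFrame:
    """Labelled 47-feature dataset with mutation-to-chain multiplicity.

    Each mutation key gets a base feature vector; deleterious (PD) keys
    are shifted by `effect_size` on the informative feature subset.  The
    key's rows (one per mapped chain) share the base vector plus small
    jitter, emulating the same mutation observed on multiple PDB chains.
    """
    rng = np.random.default_rng(seed)
    n_pd = int(round(n_keys * pd_fraction))
    labels = np.array(["PD"] * n_pd + ["SNP"] * (n_keys - n_pd))
    rng.shuffle(labels)
    informative_idx = [FEATURE_NAMES.index(f) for f in INFORMATIVE]
    pair_idx = [(FEATURE_NAMES.index(a), FEATURE_NAMES.index(b))
                for a, b in INTERACTING]
    amp = 1.5 * effect_size
    rows = []
    for i in range(n_keys):
        base = rng.normal(0.0, 1.0, len(FEATURE_NAMES))
        if labels[i] == "PD":
            base[informative_idx] += effect_size
        for ia, ib in pair_idx:
            s = rng.choice((-1.0, 1.0))
            base[ia] += s * amp
            base[ib] += (s if labels[i] == "PD" else -s) * amp
        for c in range(chains_per_key):
            vec = base + rng.normal(0.0, jitter, len(FEATURE_NAMES))
            row = {"mutation_key": f"mut{i:05d}",
                   "structure": f"pdb{i % 97:04d}",
                   "chain": chr(ord("A") + c),
                   "label": labels[i]}
            row.update(zip(FEATURE_NAMES, vec))
            rows.append(row)
    return pd.DataFrame(rows)
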