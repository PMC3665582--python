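"""The fourteen rule-based structural analyses and their dispatcher.

Each plugin returns an AnalysisResult with a continuous score and a
Boolean damage flag; a mutation is 'explained' when any structural
analysis flags it.  Plugins never abort the report: a failure inside one
analysis is recorded on that analysis only.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import clash_energy, ramachandran
from .config import DEFAULT_CONFIG, AnalysisConfig
from .params import (CHARGE, HYDROPHILIC, HYDROPHOBIC, ONE_TO_THREE,
                     load_hbond_atoms, load_hydropathy, load_residue_volumes,
                     vdw_entry)
from .results import ANALYSIS_NAMES, AnalysisReport, AnalysisResult
from .structure_model import (MutationSpec, Structure, backbone_dihedrals,
                              build_mutant_sidechain, relative_accessibility)

__all__ = [
    "analyze_interface", "analyze_binding", "analyze_sprotft",
    "analyze_clash", "analyze_void", "analyze_hbond", "analyze_corephilic",
    "analyze_surfacephobic", "analyze_buriedcharge", "analyze_ssgeometry",
    "analyze_impact", "run_all",
]

COUNTERCHARGE_SENTINEL = 999.0  # "no countercharge anywhere" distance


# ---------------------------------------------------------------- interface

def analyze_interface(structure: Structure, residue_id,
                      config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Interface burial: SASA lost when the rest of the complex is added
    to the residue's own chain."""
    if len(structure.chains) < 2 and not structure.het_groups:
        return AnalysisResult(
            analysis_name="interface", applicable=True, flagged=False,
            score=0.0, units="A^2", detail="single-chain structure")
    iso = relative_accessibility(structure, residue_id, "isolated_chain")
    cpx = relative_accessibility(structure, residue_id, "full_complex")
    dsasa = iso.absolute - cpx.absolute
    return AnalysisResult(
        analysis_name="interface", applicable=True,
        flagged=dsasa > config.interface_dsasa_cutoff,
        score=dsasa, units="A^2",
        detail=f"dSASA on complexation {dsasa:.1f} A^2",
        extras={"sasa_isolated": iso.absolute, "sasa_complex": cpx.absolute},
    )


# ------------------------------------------------------------------ binding

def analyze_binding(structure: Structure, residue_id,
                    config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Specific contacts: residue heavy atoms within `contact_distance`
    of a different chain or a (non-water) ligand."""
    res = structure.get_residue(residue_id)
    partners = []
    for other in structure.residues():
        if other.chain_id != res.chain_id:
            partners.extend(a.coords for a in other.atoms)
    for het in structure.het_groups:
        if het.id != res.id:
            partners.extend(a.coords for a in het.atoms)
    n_contact = 0
    if partners:
        tree = cKDTree(np.array(partners))
        for a in res.atoms:
            if tree.query_ball_point(a.coords, config.contact_distance):
                n_contact += 1
    return AnalysisResult(
        analysis_name="binding", applicable=True, flagged=n_contact >= 1,
        score=float(n_contact), units="atoms",
        detail=f"{n_contact} residue atoms contact another chain/ligand",
    )


# ------------------------------------------------------------------ sprotft

def analyze_sprotft(annotation_table, mutation: MutationSpec) -> AnalysisResult:
    """Annotated functional relevance from a residue-feature table with
    columns (accession, position, feature_type).  Rows match when the
    position equals the mutated residue number and the accession equals
    the structure reference or the mutation-key prefix."""
    if annotation_table is None:
        return AnalysisResult.not_applicable(
            "sprotft", detail="no annotation table supplied")
    if isinstance(annotation_table, (str, Path)):
        annotation_table = pd.read_csv(annotation_table, sep="\t",
                                       comment="#")
    accessions = {mutation.structure_ref, mutation.mutation_key.split(":")[0]}
    rows = annotation_table[
        (annotation_table["position"].astype(int) == mutation.seq_num)
        & (annotation_table["accession"].astype(str).isin(accessions))
    ]
    n = len(rows)
    features = ", ".join(map(str, rows["feature_type"])) if n else "none"
    return AnalysisResult(
        analysis_name="sprotft", applicable=True, flagged=n >= 1,
        score=float(n), units="features",
        detail=f"features at position: {features}",
    )


# -------------------------------------------------------------------- clash

def analyze_clash(structure: Structure, residue_id, mutant_aa: str,
                  config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    cr = clash_energy.sidechain_environment_energy(
        structure, residue_id, mutant_aa, config=config)
    return AnalysisResult(
        analysis_name="clash", applicable=True, flagged=cr.is_damaging,
        score=cr.total_energy, units="kcal/mol",
        detail=(f"E = {cr.total_energy:.2f} kcal/mol "
                f"(LJ {cr.lj_energy:.2f} + torsion {cr.torsion_energy:.2f}); "
                f"legacy overlap count {cr.legacy_overlap_count}"),
        extras={"lj_energy": cr.lj_energy, "torsion_energy": cr.torsion_energy,
                "legacy_overlap_count": float(cr.legacy_overlap_count),
                "legacy_damaging": cr.legacy_damaging},
    )


# --------------------------------------------------------------------- void

def _ball(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    if r < 1:
        return ndimage.generate_binary_structure(3, 1)
    ax = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X * X + Y * Y + Z * Z <= radius_cells * radius_cells


def analyze_void(structure: Structure, residue_id, mutant_aa: str,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Grid estimate of the internal cavity created next to the mutated
    residue after the large-to-small replacement.

    Grid points not inside any atom's vdW sphere and not reachable by a
    1.4 A probe flood-filled from the box boundary are void; 6-connected
    clusters adjacent to the mutated residue are measured and the largest
    volume reported.
    """
    res = structure.get_residue(residue_id)
    mutant = build_mutant_sidechain(structure, residue_id, mutant_aa)

    coords, radii = [], []
    for other in structure.residues():
        if other.id == res.id:
            continue
        for a in other.atoms:
            coords.append(a.coords)
            radii.append(vdw_entry(a.element).vdw_radius)
    for het in structure.het_groups:
        for a in het.atoms:
            coords.append(a.coords)
            radii.append(vdw_entry(a.element).vdw_radius)
    for a in mutant.atoms:
        coords.append(a.coords)
        radii.append(vdw_entry(a.element).vdw_radius)
    coords = np.array(coords)
    radii = np.array(radii)

    g = config.void_grid
    res_coords = res.coord_array()
    lo = res_coords.min(axis=0) - config.void_box_margin
    hi = res_coords.max(axis=0) + config.void_box_margin
    axes = [np.arange(lo[d] + g / 2, hi[d], g) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid_tree = cKDTree(pts)

    occupied = np.zeros(pts.shape[0], bool)
    probe_blocked = np.zeros(pts.shape[0], bool)
    probe = config.probe_radius
    for xyz, r in zip(coords, radii):
        if np.any(xyz < lo - r - probe) or np.any(xyz > hi + r + probe):
            continue
        occupied[grid_tree.query_ball_point(xyz, r)] = True
        probe_blocked[grid_tree.query_ball_point(xyz, r + probe)] = True
    occupied = occupied.reshape(shape)
    probe_free = (~probe_blocked).reshape(shape)

    six = ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(probe_free, structure=six)
    boundary = np.zeros(shape, bool)
    for d in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[d] = edge
            boundary[tuple(sl)] = True
    solvent_labels = np.unique(labels[boundary & probe_free])
    solvent_labels = solvent_labels[solvent_labels != 0]
    solvent = np.isin(labels, solvent_labels)
    # grow the solvent region by the probe radius (plus half a cell of
    # discretisation slack) so the accessible surface shell between the
    # vdW and probe-expanded surfaces is not mistaken for cavity
    solvent = ndimage.binary_dilation(solvent, structure=_ball(probe / g + 0.9))

    void = ~occupied & ~solvent
    clusters, n_clusters = ndimage.label(void, structure=six)

    near = np.zeros(pts.shape[0], bool)
    probe_atoms = list(res.atoms) + list(mutant.atoms)
    for a in probe_atoms:
        near[grid_tree.query_ball_point(a.coords, 4.0)] = True
    near = near.reshape(shape)

    score = 0.0
    for lab in range(1, n_clusters + 1):
        mask = clusters == lab
        if np.any(mask & near):
            score = max(score, float(mask.sum()) * g ** 3)

    return AnalysisResult(
        analysis_name="void", applicable=True,
        flagged=score > config.void_volume_cutoff,
        score=score, units="A^3",
        detail=f"largest adjacent void {score:.0f} A^3",
    )


# -------------------------------------------------------------------- hbond

def _covalent_neighbour(res, atom):
    best, best_d = None, 1.9
    for other in res.atoms:
        if other.name == atom.name:
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    return best


def analyze_hbond(structure: Structure, residue_id, mutant_aa: str,
                  config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Hydrogen bonds made by native sidechain donor/acceptor atoms that
    the mutant sidechain cannot maintain.

    Heavy-atom criterion: donor-acceptor distance <= hbond_distance and
    the angle between the bond axis and each partner's covalent
    neighbour >= hbond_min_angle.  A bond survives the mutation when the
    mutant sidechain carries an atom of the same functional group
    (e.g. Ser OG and Thr OG1 are both hydroxyls).
    """
    table = load_hbond_atoms()
    res = structure.get_residue(residue_id)
    own = table.get(res.aa_type, {})
    mutant3 = ONE_TO_THREE[mutant_aa.upper()]
    mutant_groups = {grp for _, grp in table.get(mutant3, {}).values()}

    # candidate partner polar atoms: backbone N (donor) / O (acceptor) and
    # sidechain polar atoms of every other residue, plus het N/O/S atoms
    partners = []
    for other in structure.residues():
        if other.id == res.id:
            continue
        for a in other.atoms:
            if a.name == "N":
                partners.append((other, a, "donor"))
            elif a.name == "O":
                partners.append((other, a, "acceptor"))
            else:
                role_grp = table.get(other.aa_type, {}).get(a.name)
                if role_grp:
                    partners.append((other, a, role_grp[0]))
    for het in structure.het_groups:
        for a in het.atoms:
            if a.element in ("N", "O", "S"):
                partners.append((het, a, "both"))

    def compatible(r1, r2):
        return (r1 in ("donor", "both") and r2 in ("acceptor", "both")) or \
               (r1 in ("acceptor", "both") and r2 in ("donor", "both"))

    bonds = []
    for name, (role, group) in own.items():
        atom = res.atom(name)
        if atom is None:
            continue
        for other, patom, prole in partners:
            if not compatible(role, prole):
                continue
            d = float(np.linalg.norm(atom.coords - patom.coords))
            if d > config.hbond_distance:
                continue
            ok = True
            for end_res, end_atom, far_atom in ((res, atom, patom),
                                                (other, patom, atom)):
                nb = _covalent_neighbour(end_res, end_atom)
                if nb is not None:
                    v1 = far_atom.coords - end_atom.coords
                    v2 = nb.coords - end_atom.coords
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang < config.hbond_min_angle:
                        ok = False
                        break
            if ok:
                bonds.append((name, group, f"{other!r}/{patom.name}", d))

    lost = [b for b in bonds if b[1] not in mutant_groups]
    return AnalysisResult(
        analysis_name="hbond", applicable=True, flagged=len(lost) >= 1,
        score=float(len(lost)), units="bonds",
        detail=(f"{len(bonds)} sidechain H-bonds, {len(lost)} lost on "
                f"mutation: " + "; ".join(f"{b[0]}->{b[2]} ({b[3]:.2f} A)"
                                          for b in lost)) if bonds
        else "no sidechain hydrogen bonds",
        extras={"n_bonds_native": float(len(bonds))},
    )


# ------------------------------------------------- corephilic/surfacephobic

def _hydropathy_result(name: str, structure, residue_id, mutant_aa,
                       config: AnalysisConfig) -> AnalysisResult:
    res = structure.get_residue(residue_id)
    native_aa = res.aa1
    if native_aa is None:
        return AnalysisResult.not_applicable(name, detail="non-standard residue")
    acc = relative_accessibility(structure, residue_id, "full_complex")
    in_core = acc.relative <= config.core_rel_access
    table = load_hydropathy()
    kd_nat, _ = table[native_aa]
    kd_mut, _ = table[mutant_aa.upper()]
    if name == "corephilic":
        flagged = (in_core and mutant_aa.upper() in HYDROPHILIC
                   and native_aa not in HYDROPHILIC)
        location = "core" if in_core else "surface"
    else:
        flagged = (not in_core and mutant_aa.upper() in HYDROPHOBIC
                   and native_aa not in HYDROPHOBIC)
        location = "surface" if not in_core else "core"
    return AnalysisResult(
        analysis_name=name, applicable=True, flagged=flagged,
        score=kd_mut - kd_nat, units="KD units",
        detail=(f"residue in {location} (rel. acc. {acc.relative:.2f}); "
                f"hydropathy {kd_nat:+.1f} -> {kd_mut:+.1f}"),
        extras={"rel_access": acc.relative, "kd_native": kd_nat,
                "kd_mutant": kd_mut},
    )


def analyze_corephilic(structure, residue_id, mutant_aa,
                       config: AnalysisConfig = DEFAULT_CONFIG):
    """Hydrophilic residue introduced into the hydrophobic core."""
    return _hydropathy_result("corephilic", structure, residue_id,
                              mutant_aa, config)


def analyze_surfacephobic(structure, residue_id, mutant_aa,
                          config: AnalysisConfig = DEFAULT_CONFIG):
    """Hydrophobic residue introduced on the solvent-exposed surface."""
    return _hydropathy_result("surfacephobic", structure, residue_id,
                              mutant_aa, config)


# ------------------------------------------------------------- buriedcharge

CHARGED_ATOMS = {
    "ASP": {"OD1": -1, "OD2": -1}, "GLU": {"OE1": -1, "OE2": -1},
    "LYS": {"NZ": +1}, "ARG": {"NE": +1, "NH1": +1, "NH2": +1},
}


def _nearest_countercharge(structure, exclude_id, from_atoms, sign) -> float:
    """Distance from any of `from_atoms` to the nearest charged atom of
    opposite sign elsewhere in the structure."""
    best = COUNTERCHARGE_SENTINEL
    for other in structure.residues():
        if other.id == exclude_id:
            continue
        charged = CHARGED_ATOMS.get(other.aa_type, {})
        for nm, s in charged.items():
            if s * sign >= 0:
                continue
            a = other.atom(nm)
            if a is None:
                continue
            for fa in from_atoms:
                best = min(best, float(np.linalg.norm(fa.coords - a.coords)))
    return best


def analyze_buriedcharge(structure, residue_id, mutant_aa,
                         config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Unsatisfied charge in the core: either the mutant buries a new
    charge with no countercharge within contact distance, or the mutation
    removes one partner of a buried salt bridge."""
    res = structure.get_residue(residue_id)
    native_aa = res.aa1
    mutant_aa = mutant_aa.upper()
    acc = relative_accessibility(structure, residue_id, "full_complex")
    in_core = acc.relative <= config.core_rel_access
    native_q = CHARGE.get(native_aa, 0)
    mutant_q = CHARGE.get(mutant_aa, 0)

    flagged = False
    dist = COUNTERCHARGE_SENTINEL
    why = "no buried-charge rule triggered"
    if in_core and mutant_q != 0 and native_q == 0:
        mutant = build_mutant_sidechain(structure, residue_id, mutant_aa)
        charged_names = CHARGED_ATOMS[mutant.aa_type]
        atoms = [mutant.atom(nm) for nm in charged_names if mutant.atom(nm)]
        dist = _nearest_countercharge(structure, res.id, atoms, mutant_q)
        flagged = dist > config.contact_distance
        why = (f"buried {mutant_aa} charge; nearest countercharge "
               f"{dist:.1f} A" if dist < COUNTERCHARGE_SENTINEL
               else f"buried {mutant_aa} charge; no countercharge present")
    elif in_core and native_q != 0 and mutant_q == 0:
        charged_names = CHARGED_ATOMS.get(res.aa_type, {})
        atoms = [res.atom(nm) for nm in charged_names if res.atom(nm)]
        dist = _nearest_countercharge(structure, res.id, atoms, native_q)
        flagged = dist <= config.contact_distance
        why = (f"buried salt bridge at {dist:.1f} A broken by uncharged "
               f"{mutant_aa}" if flagged
               else "native buried charge has no salt-bridge partner")
    return AnalysisResult(
        analysis_name="buriedcharge", applicable=True, flagged=flagged,
        score=dist, units="A", detail=why,
        extras={"rel_access": acc.relative, "native_charge": float(native_q),
                "mutant_charge": float(mutant_q)},
    )


# --------------------------------------------------------------- ssgeometry

def analyze_ssgeometry(structure, residue_id, mutant_aa,
                       config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    res = structure.get_residue(residue_id)
    if res.aa_type != "CYS":
        return AnalysisResult.not_applicable(
            "ssgeometry", detail="native is not cysteine")
    sg = res.atom("SG")
    if sg is None:
        return AnalysisResult.not_applicable("ssgeometry", detail="SG missing")
    best = np.inf
    partner = None
    for other in structure.residues():
        if other.id == res.id or other.aa_type != "CYS":
            continue
        osg = other.atom("SG")
        if osg is None:
            continue
        d = float(np.linalg.norm(sg.coords - osg.coords))
        if d < best:
            best, partner = d, other
    if partner is None:
        return AnalysisResult(
            analysis_name="ssgeometry", applicable=True, flagged=False,
            score=COUNTERCHARGE_SENTINEL, units="A",
            detail="no other cysteine in structure")
    bonded = best <= config.ss_distance
    flagged = bonded and mutant_aa.upper() != "C"
    return AnalysisResult(
        analysis_name="ssgeometry", applicable=True, flagged=flagged,
        score=best, units="A",
        detail=f"nearest SG ({partner!r}) at {best:.2f} A"
               + (" - disulphide broken" if flagged else ""),
    )


# ------------------------------------------------------------------- impact

def analyze_impact(msa, column: Optional[int], native_aa: str,
                   mutant_aa: str,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> AnalysisResult:
    """Column conservation from a multiple sequence alignment.

    The score is a normalised Shannon information measure,
    1 - H(column)/ln(20), so 1 means invariant and 0 a uniform column;
    it stands in for the conservation scoring of the original pipeline
    (metadata labels it as such).  `column` is 0-based.
    """
    if msa is None or column is None:
        return AnalysisResult.not_applicable(
            "impact", detail="no alignment supplied")
    if isinstance(msa, (str, Path)):
        from Bio import AlignIO
        msa = [str(rec.seq) for rec in AlignIO.read(str(msa), "fasta")]
    else:
        msa = [str(s) for s in msa]
    letters = [s[column].upper() for s in msa
               if column < len(s) and s[column].upper() in ONE_TO_THREE]
    if not letters:
        return AnalysisResult.not_applicable(
            "impact", detail="alignment column empty")
    _, counts = np.unique(letters, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    score = 1.0 - entropy / np.log(20.0)
    return AnalysisResult(
        analysis_name="impact", applicable=True,
        flagged=score >= config.conservation_cutoff,
        score=score, units="normalised conservation",
        detail=(f"conservation {score:.3f} over {len(letters)} sequences "
                f"(entropy stand-in score)"),
        extras={"n_sequences": float(len(letters))},
    )


# ------------------------------------------------------------------ run_all

def run_all(structure: Structure, mutation: MutationSpec,
            maps=None, config: AnalysisConfig = DEFAULT_CONFIG,
            annotations=None, msa=None, msa_column=None) -> AnalysisReport:
    """Dispatch all fourteen analyses for one mutation.

    The native amino acid is checked against the structure before
    dispatch (hard error); afterwards a failure inside any single plugin
    is recorded on that analysis without aborting the report.
    """
    mutation.check_against(structure)
    rid = mutation.residue_id
    mut = mutation.mutant_aa
    dihedrals = backbone_dihedrals(structure, rid)

    def guard(name, fn):
        try:
            return fn()
        except Exception as exc:  # per-plugin failure containment
            return AnalysisResult.not_applicable(
                name, detail=f"analysis failed: {exc}")

    dispatch = {
        "interface": lambda: analyze_interface(structure, rid, config),
        "binding": lambda: analyze_binding(structure, rid, config),
        "sprotft": lambda: analyze_sprotft(annotations, mutation),
        "clash": lambda: analyze_clash(structure, rid, mut, config),
        "void": lambda: analyze_void(structure, rid, mut, config),
        "cisproline": lambda: ramachandran.assess_cis_proline(
            dihedrals, mutation.native_aa, mut, cis_omega=config.cis_omega),
        "glycine": lambda: (
            ramachandran.assess_backbone_mutation(
                dihedrals, mutation.native_aa, mut, maps, "glycine")
            if maps is not None else AnalysisResult.not_applicable(
                "glycine", detail="no reference maps supplied")),
        "proline": lambda: (
            ramachandran.assess_backbone_mutation(
                dihedrals, mutation.native_aa, mut, maps, "proline")
            if maps is not None else AnalysisResult.not_applicable(
                "proline", detail="no reference maps supplied")),
        "hbond": lambda: analyze_hbond(structure, rid, mut, config),
        "corephilic": lambda: analyze_corephilic(structure, rid, mut, config),
        "surfacephobic": lambda: analyze_surfacephobic(
            structure, rid, mut, config),
        "buriedcharge": lambda: analyze_buriedcharge(
            structure, rid, mut, config),
        "ssgeometry": lambda: analyze_ssgeometry(structure, rid, mut, config),
        "impact": lambda: analyze_impact(
            msa, msa_column, mutation.native_aa, mut, config),
    }
    results = [guard(name, dispatch[name]) for name in ANALYSIS_NAMES]
    return AnalysisReport(mutation=mutation, results=results)
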