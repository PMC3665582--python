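"""Sidechain-replacement clash pseudo-energy.

The score for a candidate mutant sidechain is

    E = sum_pairs (A/r^12 - B/r^6) + sum_chis k (1 + cos(n*psi + phase))

i.e. a 12-6 Lennard-Jones term over every (mutant sidechain heavy atom,
environment heavy atom) pair within a cutoff, plus a torsion term per
sidechain chi expressing the preference for staggered rotamers.  A
mutation is called damaging when the total exceeds the configured
cutoff (34.33 kcal/mol by default; 13.4 kcal/mol as the stricter
99th-percentile preset).

The legacy Boolean rule — at least three van der Waals overlaps of any
depth — is kept as a comparator: it misses deep two-atom clashes and
over-calls three grazing contacts, which the energy resolves.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import templates
from .config import DEFAULT_CONFIG, AnalysisConfig
from .params import (ONE_TO_THREE, TorsionParams, load_torsion_table,
                     load_vdw_table, vdw_entry)
from .structure_model import Structure, build_mutant_sidechain, sidechain_chis

__all__ = [
    "PairParams", "ClashResult", "pair_params", "lj_pair_energy",
    "torsion_term", "sidechain_environment_energy", "legacy_clash_count",
]


@dataclass(frozen=True)
class PairParams:
    """LJ coefficients for one atom-type pair, Lorentz-Berthelot combined:
    Rmin_ij = Rmin_i/2 + Rmin_j/2, eps_ij = sqrt(eps_i eps_j), so that
    E(Rmin_ij) = -eps_ij exactly with A = eps Rmin^12, B = 2 eps Rmin^6."""
    rmin: float
    epsilon: float

    @property
    def A(self) -> float:
        return self.epsilon * self.rmin ** 12

    @property
    def B(self) -> float:
        return 2.0 * self.epsilon * self.rmin ** 6


def pair_params(element_i: str, element_j: str, table=None) -> PairParams:
    ei = vdw_entry(element_i, table)
    ej = vdw_entry(element_j, table)
    return PairParams(rmin=ei.rmin_half + ej.rmin_half,
                      epsilon=float(np.sqrt(ei.epsilon * ej.epsilon)))


def lj_pair_energy(r: float, params: PairParams,
                   floor: float = DEFAULT_CONFIG.lj_floor) -> float:
    """12-6 energy A/r^12 - B/r^6 in kcal/mol; r below `floor` is
    evaluated at the floor to avoid overflow."""
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    r = max(r, floor)
    return params.A / r ** 12 - params.B / r ** 6


def torsion_term(psi_deg: float, params: TorsionParams) -> float:
    """k (1 + cos(n psi + phase)) in kcal/mol; psi and phase in degrees."""
    return params.k * (1.0 + np.cos(np.radians(params.n * psi_deg + params.phase)))


@dataclass
class ClashResult:
    total_energy: float
    lj_energy: float
    torsion_energy: float
    legacy_overlap_count: int
    is_damaging: bool
    legacy_damaging: bool
    contacts: list = field(default_factory=list)  # (mut_atom, env_label, r, E)
    floored: bool = False

    def __post_init__(self):
        assert abs(self.total_energy - (self.lj_energy + self.torsion_energy)) < 1e-9


def _environment(structure: Structure, residue_id):
    """All heavy atoms outside the mutated residue (other residues of
    every chain plus non-water het groups)."""
    target = structure.get_residue(residue_id).id
    atoms = []
    for res in structure.residues():
        if res.id == target:
            continue
        atoms.extend((res, a) for a in res.atoms)
    for het in structure.het_groups:
        atoms.extend((het, a) for a in het.atoms)
    return atoms


def sidechain_environment_energy(structure: Structure, residue_id,
                                 mutant_aa: str,
                                 config: AnalysisConfig = DEFAULT_CONFIG,
                                 vdw_table=None,
                                 torsion_table=None) -> ClashResult:
    """Evaluate the clash pseudo-energy of placing `mutant_aa` at a
    residue position.  The mutated residue's own backbone is excluded
    from the LJ sum; torsions are evaluated on the mutant chis."""
    vdw_table = vdw_table or load_vdw_table()
    torsion_table = torsion_table or load_torsion_table()
    mutant = build_mutant_sidechain(structure, residue_id, mutant_aa)
    side = mutant.sidechain_atoms()
    env = _environment(structure, residue_id)

    lj = 0.0
    contacts = []
    floored = False
    if side and env:
        env_coords = np.array([a.coords for _, a in env])
        tree = cKDTree(env_coords)
        for atom in side:
            for j in tree.query_ball_point(atom.coords, config.lj_cutoff):
                env_res, env_atom = env[j]
                r = float(np.linalg.norm(atom.coords - env_atom.coords))
                if r < config.lj_floor:
                    floored = True
                pp = pair_params(atom.element, env_atom.element, vdw_table)
                e = lj_pair_energy(r, pp, floor=config.lj_floor)
                lj += e
                contacts.append((atom.name, f"{env_res!r}/{env_atom.name}", r, e))

    torsion = 0.0
    mut3 = ONE_TO_THREE[mutant_aa.upper()]
    for k, chi in enumerate(sidechain_chis(mutant)):
        if chi is None:
            continue
        cls = "planar" if (mut3, k + 1) in templates.PLANAR_CHIS else "sp3"
        torsion += torsion_term(chi, torsion_table[cls])

    total = lj + torsion
    legacy = legacy_clash_count(structure, residue_id, mutant_aa,
                                vdw_table=vdw_table, mutant=mutant)
    return ClashResult(
        total_energy=total, lj_energy=lj, torsion_energy=torsion,
        legacy_overlap_count=legacy["count"],
        is_damaging=total > config.clash_energy_cutoff,
        legacy_damaging=legacy["damaging"],
        contacts=contacts, floored=floored,
    )


def legacy_clash_count(structure: Structure, residue_id, mutant_aa: str,
                       vdw_table=None, mutant=None) -> dict:
    """Legacy Boolean rule: count environment atoms overlapping any
    mutant sidechain atom (distance < sum of vdW radii, depth ignored);
    damaging iff count >= 3."""
    vdw_table = vdw_table or load_vdw_table()
    if mutant is None:
        mutant = build_mutant_sidechain(structure, residue_id, mutant_aa)
    side = mutant.sidechain_atoms()
    env = _environment(structure, residue_id)
    count = 0
    if side and env:
        side_coords = np.array([a.coords for a in side])
        side_radii = np.array([vdw_entry(a.element, vdw_table).vdw_radius
                               for a in side])
        for _, env_atom in env:
            r_env = vdw_entry(env_atom.element, vdw_table).vdw_radius
            d = np.linalg.norm(side_coords - env_atom.coords, axis=1)
            if np.any(d < side_radii + r_env):
                count += 1
    return {"count": count, "damaging": count >= 3}
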