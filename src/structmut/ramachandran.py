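"""Ramachandran pseudo-energy maps for glycine, proline and 'other'
residues.

Backbone (phi, psi) observations are binned on a 1-degree grid, smoothed
by averaging each cell with its eight toroidal neighbours, and turned
into a pseudo-energy E = -ln(obs/exp) where exp is the mean count per
cell.  A per-map threshold is set so that at most 1% of the input
observations fall in cells with a worse (higher) energy.  Mutations from
glycine and to proline are then scored by the energy of the native
backbone conformation in the map of the mutant's residue class.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .results import AnalysisResult
from .structure_model import Dihedrals, Structure, backbone_dihedrals

__all__ = [
    "GRID", "OBS_FLOOR", "RamaMap", "RamaMapSet", "residue_class",
    "bin_index", "accumulate_counts", "smooth", "cell_energy",
    "threshold_energy", "build_maps_from_observations",
    "build_reference_maps", "assess_backbone_mutation", "assess_cis_proline",
]

GRID = 360
OBS_FLOOR = 0.1   # smoothed-count floor applied before the log
CLASSES = ("glycine", "proline", "other")


def residue_class(aa1: str) -> str:
    return {"G": "glycine", "P": "proline"}.get(aa1.upper(), "other")


def bin_index(angle_deg: float) -> int:
    """Cell index for one angle: half-open 1-degree cells anchored at
    -180, so cell i covers [-180+i, -180+i+1); +180 wraps to cell 0."""
    return int(np.floor((angle_deg + 180.0) % 360.0))


@dataclass
class RamaMap:
    residue_class: str
    counts: np.ndarray                 # (360, 360) raw observation counts
    smoothed: np.ndarray = None
    energy: np.ndarray = None
    exp: float = 0.0                   # expected count per cell
    threshold: float = 0.0
    n_obs: int = 0
    n_skipped: int = 0

    def finalise(self):
        """Smooth, energise and threshold the raw counts."""
        self.n_obs = int(round(self.counts.sum()))
        if self.n_obs == 0:
            raise ValueError(
                f"no observations for residue class {self.residue_class!r}")
        self.smoothed = smooth(self.counts)
        self.exp = self.n_obs / (GRID * GRID)
        self.energy = cell_energy(self.smoothed, self.exp)
        self.threshold = threshold_energy(self)
        return self

    def lookup(self, phi: float, psi: float) -> float:
        return float(self.energy[bin_index(phi), bin_index(psi)])


def accumulate_counts(observations) -> tuple:
    """Bin (phi, psi, residue_class) observations into per-class count
    grids.  Observations with undefined phi or psi are skipped and the
    skip count reported.

    Returns ({class: counts}, {class: n_skipped}).
    """
    grids = {c: np.zeros((GRID, GRID)) for c in CLASSES}
    skipped = {c: 0 for c in CLASSES}
    for phi, psi, cls in observations:
        if cls not in grids:
            raise ValueError(f"unknown residue class {cls!r}")
        if phi is None or psi is None:
            skipped[cls] += 1
            continue
        grids[cls][bin_index(phi), bin_index(psi)] += 1
    return grids, skipped


def smooth(counts: np.ndarray) -> np.ndarray:
    """Mean of each cell with its eight neighbours, wrapping at +-180 on
    both axes (the plot is a torus).  Conserves the grand total."""
    return ndimage.uniform_filter(np.asarray(counts, float), size=3, mode="wrap")


def cell_energy(smoothed_obs, exp: float):
    """Pseudo-energy -ln(obs/exp), with obs floored at OBS_FLOOR so empty
    cells get a finite cap of ln(exp/0.1)."""
    if exp <= 0:
        raise ValueError("expected count must be positive (empty map?)")
    obs = np.maximum(np.asarray(smoothed_obs, float), OBS_FLOOR)
    return -np.log(obs / exp)


def threshold_energy(rmap: RamaMap) -> float:
    """Observation-weighted 99th-percentile energy: the smallest cell
    energy such that at most 1% of the input observations sit in cells
    with strictly higher energy."""
    if rmap.n_obs == 0:
        raise ValueError("cannot threshold an empty map")
    counts = rmap.counts.ravel()
    nonzero = counts > 0
    energies = cell_energy(smooth(rmap.counts), rmap.n_obs / (GRID * GRID)) \
        if rmap.energy is None else rmap.energy
    cell_e = energies.ravel()[nonzero]
    weights = counts[nonzero].astype(np.int64)
    per_obs = np.repeat(cell_e, weights)
    per_obs.sort()
    n = per_obs.size
    idx = int(np.ceil(0.99 * n)) - 1
    return float(per_obs[idx])


def build_maps_from_observations(observations) -> "RamaMapSet":
    """Build, smooth, energise and threshold all three class maps from
    (phi, psi, class) observations."""
    grids, skipped = accumulate_counts(observations)
    maps = {}
    for cls in CLASSES:
        rmap = RamaMap(residue_class=cls, counts=grids[cls],
                       n_skipped=skipped[cls])
        maps[cls] = rmap.finalise()
    return RamaMapSet(maps)


def build_reference_maps(structures, max_resolution: Optional[float] = 1.8
                         ) -> "RamaMapSet":
    """Build the three reference maps from a set of structures.

    `structures` may be Structure objects or PDB paths.  Structures whose
    parsed resolution is known and worse than `max_resolution` are
    excluded; redundancy filtering is an upstream curation step.
    """
    from .structure_model import read_pdb  # local to avoid import cycle noise
    observations = []
    for item in structures:
        s = item if isinstance(item, Structure) else read_pdb(item)
        if (max_resolution is not None and s.resolution is not None
                and s.resolution > max_resolution):
            continue
        for res in s.residues():
            if res.aa1 is None:
                continue
            d = backbone_dihedrals(s, res.id)
            observations.append((d.phi, d.psi, residue_class(res.aa1)))
    return build_maps_from_observations(observations)


@dataclass
class RamaMapSet:
    maps: dict = field(default_factory=dict)
    version: str = "1"

    def __getitem__(self, cls: str) -> RamaMap:
        return self.maps[cls]

    def save(self, path):
        arrays = {"version": np.array(self.version)}
        for cls, m in self.maps.items():
            arrays[f"{cls}_counts"] = m.counts
            arrays[f"{cls}_meta"] = np.array(
                [m.exp, m.threshold, m.n_obs, m.n_skipped])
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "RamaMapSet":
        data = np.load(path, allow_pickle=False)
        maps = {}
        for c in CLASSES:
            m = RamaMap(residue_class=c, counts=data[f"{c}_counts"])
            m.finalise()
            # meta is recomputed; stored values are a consistency check
            exp, threshold, n_obs, n_skipped = data[f"{c}_meta"]
            m.n_skipped = int(n_skipped)
            maps[c] = m
        return cls(maps, version=str(data["version"]))


def assess_backbone_mutation(dihedrals: Dihedrals, native_aa: str,
                             mutant_aa: str, maps: RamaMapSet,
                             which: str) -> AnalysisResult:
    """Score a from-glycine ('glycine') or to-proline ('proline')
    mutation against the map of the mutant's residue class.

    The continuous score is the mutant-class energy at the native
    (phi, psi); the flag fires when it exceeds that map's threshold.
    The native-class energy and the difference are reported alongside.
    """
    if which not in ("glycine", "proline"):
        raise ValueError(which)
    native_aa, mutant_aa = native_aa.upper(), mutant_aa.upper()
    applies = (native_aa == "G" and mutant_aa != "G") if which == "glycine" \
        else (mutant_aa == "P" and native_aa != "P")
    if not applies:
        return AnalysisResult.not_applicable(
            which, detail="rule does not apply to this substitution")
    if dihedrals.phi is None or dihedrals.psi is None:
        return AnalysisResult.not_applicable(
            which, detail="phi/psi undefined (chain terminus)")

    mutant_cls = residue_class(mutant_aa)
    native_cls = residue_class(native_aa)
    e_mut = maps[mutant_cls].lookup(dihedrals.phi, dihedrals.psi)
    e_nat = maps[native_cls].lookup(dihedrals.phi, dihedrals.psi)
    thr = maps[mutant_cls].threshold
    return AnalysisResult(
        analysis_name=which, applicable=True, flagged=e_mut > thr,
        score=e_mut, units="pseudo-energy",
        detail=(f"{mutant_cls}-map energy {e_mut:.2f} at "
                f"(phi={dihedrals.phi:.1f}, psi={dihedrals.psi:.1f}); "
                f"threshold {thr:.2f}"),
        extras={"native_class_energy": e_nat, "mutant_class_energy": e_mut,
                "delta_energy": e_mut - e_nat, "threshold": thr},
    )


def assess_cis_proline(dihedrals: Dihedrals, native_aa: str, mutant_aa: str,
                       cis_omega: float = 30.0) -> AnalysisResult:
    """Flag mutations away from a cis-proline (|omega| <= cis_omega)."""
    native_aa, mutant_aa = native_aa.upper(), mutant_aa.upper()
    if native_aa != "P" or mutant_aa == "P":
        return AnalysisResult.not_applicable(
            "cisproline", detail="native is not proline")
    if dihedrals.omega is None:
        return AnalysisResult.not_applicable(
            "cisproline", detail="omega undefined (chain start)")
    is_cis = abs(dihedrals.omega) <= cis_omega
    return AnalysisResult(
        analysis_name="cisproline", applicable=True, flagged=is_cis,
        score=abs(dihedrals.omega), units="deg",
        detail=f"|omega| = {abs(dihedrals.omega):.1f} deg "
               f"({'cis' if is_cis else 'trans'})",
        extras={"omega": dihedrals.omega},
    )
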