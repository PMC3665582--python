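"""Solvent-accessible surface area by the Shrake-Rupley rolling-probe
method, and extended Gly-X-Gly reference accessibilities.

The probe radius defaults to 1.4 Angstrom (water) with 960 test points
per atom sphere.
"""
from __future__ import annotations

import functools

import numpy as np
from scipy.spatial import cKDTree

from . import templates
from .params import element_of, vdw_entry

__all__ = ["sphere_points", "shrake_rupley", "gxg_reference"]

PROBE_RADIUS = 1.4
N_POINTS = 960


@functools.lru_cache(maxsize=4)
def sphere_points(n: int = N_POINTS) -> np.ndarray:
    """Near-uniform unit-sphere points via the golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(coords, radii, probe: float = PROBE_RADIUS,
                  n_points: int = N_POINTS) -> np.ndarray:
    """Per-atom SASA in square Angstrom.

    coords: (N, 3) heavy-atom coordinates; radii: (N,) vdW radii.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.ndim != 2 or coords.shape[0] != radii.shape[0]:
        raise ValueError("coords/radii shape mismatch")
    n = coords.shape[0]
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(n)
    for i in range(n):
        surface = coords[i] + expanded[i] * pts
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                      if j != i]
        if neighbours:
            d = np.linalg.norm(
                surface[:, None, :] - coords[neighbours][None, :, :], axis=2
            )
            buried = (d < expanded[neighbours][None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible / n_points
    return areas


@functools.lru_cache(maxsize=32)
def gxg_reference(aa: str, probe: float = PROBE_RADIUS) -> float:
    """SASA of residue X in an extended Gly-X-Gly tripeptide (Angstrom^2).

    The denominator of relative accessibility; computed once per residue
    type from the ideal-geometry builder and cached.
    """
    residues = templates.build_peptide("G" + aa.upper() + "G",
                                       phi=-139.0, psi=135.0)
    coords, radii, owner = [], [], []
    for ridx, (_, atoms) in enumerate(residues):
        for name, xyz in atoms.items():
            coords.append(xyz)
            radii.append(vdw_entry(element_of(name)).vdw_radius)
            owner.append(ridx)
    areas = shrake_rupley(np.array(coords), np.array(radii), probe=probe)
    owner = np.array(owner)
    return float(areas[owner == 1].sum())
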