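"""Analysis thresholds and numerical settings, in one place.

Two thresholds come from the published calibration of the method (the
34.33 kcal/mol clash-energy cutoff, with 13.4 kcal/mol available as the
stricter 99th-percentile preset, and the 275 A^3 destabilising-void
volume).  The remaining cutoffs are conventional structural-biology
choices; `threshold_provenance` records which is which so reports can
echo it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

CLASH_ENERGY_CUTOFF = 34.33       # kcal/mol, calibrated default
CLASH_ENERGY_CUTOFF_STRICT = 13.4  # kcal/mol, 99th-percentile preset
VOID_VOLUME_CUTOFF = 275.0        # A^3


@dataclass
class AnalysisConfig:
    clash_energy_cutoff: float = CLASH_ENERGY_CUTOFF   # kcal/mol
    void_volume_cutoff: float = VOID_VOLUME_CUTOFF     # A^3
    interface_dsasa_cutoff: float = 10.0               # A^2
    contact_distance: float = 4.0                      # A, binding / salt bridge
    hbond_distance: float = 3.5                        # A donor-acceptor
    hbond_min_angle: float = 90.0                      # deg D-A-(A neighbour)
    ss_distance: float = 2.5                           # A SG-SG
    core_rel_access: float = 0.10                      # relative accessibility
    conservation_cutoff: float = 0.9                   # normalised score
    cis_omega: float = 30.0                            # deg, |omega| for cis
    lj_cutoff: float = 8.0                             # A pair cutoff
    lj_floor: float = 0.1                              # A minimum r
    void_grid: float = 1.0                             # A grid spacing
    void_box_margin: float = 16.0                      # A box around residue
    probe_radius: float = 1.4                          # A solvent probe

    threshold_provenance: dict = field(default_factory=lambda: {
        "clash_energy_cutoff": "calibrated",
        "void_volume_cutoff": "calibrated",
        "interface_dsasa_cutoff": "default",
        "contact_distance": "default",
        "hbond_distance": "default",
        "hbond_min_angle": "default",
        "ss_distance": "default",
        "core_rel_access": "default",
        "conservation_cutoff": "default",
        "cis_omega": "default",
    })


DEFAULT_CONFIG = AnalysisConfig()
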