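import numpy as np
import pytest

from structmut import fixtures as fx
from structmut import ramachandran as rama
from structmut.structure_model import Dihedrals, read_pdb


class TestBinning:
    def test_hand_binned_cell(self):
        assert rama.bin_index(-60.4) == 119
        assert rama.bin_index(-45.2) == 134

    def test_plus_180_wraps_to_minus_edge(self):
        assert rama.bin_index(180.0) == 0
        assert rama.bin_index(-180.0 + 1e-9) == 0
        assert rama.bin_index(179.5) == 359

    def test_counts_conserved_and_skips_reported(self):
        obs = [(-60.0, -45.0, "other")] * 7 + [(None, 10.0, "other")] * 2
        grids, skipped = rama.accumulate_counts(obs)
        assert grids["other"].sum() == 7
        assert skipped["other"] == 2


class TestSmoothing:
    def test_uniform_grid_unchanged(self):
        g = np.full((360, 360), 3.0)
        assert np.allclose(rama.smooth(g), g)

    def test_nine_cell_mean(self):
        g = np.zeros((360, 360))
        g[100, 100] = 9.0
        sm = rama.smooth(g)
        block = sm[99:102, 99:102]
        assert np.allclose(block, 1.0)
        assert sm.sum() == pytest.approx(9.0, abs=1e-9)

    def test_corner_wraps_toroidally_vs_bruteforce(self):
        rng = np.random.default_rng(5)
        g = np.zeros((360, 360))
        idx = rng.integers(0, 360, size=(50, 2))
        for i, j in idx:
            g[i, j] += rng.integers(1, 5)
        sm = rama.smooth(g)
        # brute-force toroidal 9-cell mean
        brute = np.zeros_like(g)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                brute += np.roll(np.roll(g, di, axis=0), dj, axis=1)
        brute /= 9.0
        assert np.allclose(sm, brute, atol=1e-12)
        assert sm.sum() == pytest.approx(g.sum(), abs=1e-9)


class TestCellEnergy:
    def test_obs_equals_exp_gives_zero(self):
        assert rama.cell_energy(10.0, 10.0) == pytest.approx(0.0)

    def test_natural_log(self):
        assert rama.cell_energy(10.0 * np.e, 10.0) == pytest.approx(-1.0)

    def test_zero_count_floor(self):
        assert rama.cell_energy(0.0, 10.0) == pytest.approx(np.log(100.0))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            rama.cell_energy(1.0, 0.0)


class TestThreshold:
    def test_single_cell_threshold_is_its_energy(self):
        counts = np.zeros((360, 360))
        counts[10, 20] = 50
        m = rama.RamaMap("other", counts).finalise()
        assert m.threshold == pytest.approx(m.energy[10, 20])

    def test_two_level_synthetic_map(self):
        """99% of observations in a tight low-energy block, 1% far away:
        the returned threshold separates the levels exactly as the
        sorted-per-observation percentile does."""
        counts = np.zeros((360, 360))
        counts[100:105, 100:105] = 9900 / 25.0
        counts[300, 300] = 100
        m = rama.RamaMap("other", counts).finalise()
        # brute-force oracle: sorted per-observation energies
        nz = np.argwhere(m.counts > 0)
        per_obs = np.concatenate([
            np.full(int(m.counts[i, j]), m.energy[i, j]) for i, j in nz])
        per_obs.sort()
        oracle = per_obs[int(np.ceil(0.99 * per_obs.size)) - 1]
        assert m.threshold == pytest.approx(oracle, abs=1e-12)
        low = m.energy[102, 102]
        high = m.energy[300, 300]
        assert low <= m.threshold < high

    def test_tail_fraction_at_most_one_percent(self):
        obs = fx.synth_dihedral_sample(10000, seed=3)
        maps = rama.build_maps_from_observations(obs)
        for cls in rama.CLASSES:
            m = maps[cls]
            above = m.counts[(m.counts > 0) & (m.energy > m.threshold)].sum()
            assert above / m.n_obs <= 0.01


class TestMapBuilding:
    def test_counts_per_class_from_structures(self, tmp_path):
        paths = [fx.make_helix(8, tmp_path / "a.pdb", sequence="AAGAPAAA"),
                 fx.make_helix(6, tmp_path / "b.pdb", sequence="GPGPGP")]
        structures = [read_pdb(p) for p in paths]
        maps = rama.build_reference_maps(structures)
        # scored residues: interior residues with both phi and psi defined
        expected = {"glycine": 0, "proline": 0, "other": 0}
        for s in structures:
            for res in s.residues():
                d = rama.backbone_dihedrals(s, res.id)
                if d.phi is not None and d.psi is not None:
                    expected[rama.residue_class(res.aa1)] += 1
        for cls in rama.CLASSES:
            assert maps[cls].n_obs == expected[cls]

    def test_empty_class_is_an_error(self, tmp_path):
        s = read_pdb(fx.make_helix(5, tmp_path / "c.pdb"))  # no Gly/Pro
        with pytest.raises(ValueError, match="glycine|proline"):
            rama.build_reference_maps([s])

    def test_serialisation_roundtrip(self, tmp_path, rama_maps):
        f = tmp_path / "maps.npz"
        rama_maps.save(f)
        loaded = rama.RamaMapSet.load(f)
        for cls in rama.CLASSES:
            assert np.array_equal(loaded[cls].counts, rama_maps[cls].counts)
            assert loaded[cls].threshold == pytest.approx(
                rama_maps[cls].threshold, abs=1e-12)

    def test_basin_cells_have_lower_energy(self, rama_maps):
        m = rama_maps["other"]
        basin = m.energy[rama.bin_index(-63.0), rama.bin_index(-43.0)]
        desert = m.energy[rama.bin_index(60.0), rama.bin_index(-120.0)]
        assert basin < desert


class TestAssessments:
    def test_glycine_in_left_handed_region_flagged(self, rama_maps):
        d = Dihedrals(phi=80.0, psi=-10.0, omega=180.0)
        r = rama.assess_backbone_mutation(d, "G", "A", rama_maps, "glycine")
        assert r.applicable and r.flagged
        assert r.score > rama_maps["other"].threshold

    def test_glycine_in_helix_region_not_flagged(self, rama_maps):
        d = Dihedrals(phi=-60.0, psi=-45.0, omega=180.0)
        r = rama.assess_backbone_mutation(d, "G", "A", rama_maps, "glycine")
        assert r.applicable and not r.flagged

    def test_non_gly_non_pro_not_applicable(self, rama_maps):
        d = Dihedrals(phi=-60.0, psi=-45.0, omega=180.0)
        assert not rama.assess_backbone_mutation(
            d, "A", "S", rama_maps, "glycine").applicable
        assert not rama.assess_backbone_mutation(
            d, "A", "S", rama_maps, "proline").applicable

    def test_to_proline_uses_proline_map(self, rama_maps):
        d = Dihedrals(phi=60.0, psi=120.0, omega=180.0)  # phi > 0: bad for Pro
        r = rama.assess_backbone_mutation(d, "A", "P", rama_maps, "proline")
        assert r.applicable and r.flagged

    def test_undefined_phi_not_applicable(self, rama_maps):
        d = Dihedrals(phi=None, psi=-45.0, omega=180.0)
        assert not rama.assess_backbone_mutation(
            d, "G", "A", rama_maps, "glycine").applicable

    @pytest.mark.parametrize("omega,native,mutant,applicable,flagged", [
        (2.0, "P", "A", True, True),
        (179.0, "P", "A", True, False),
        (2.0, "A", "S", False, False),
        (None, "P", "A", False, False),
    ])
    def test_cis_proline_rules(self, omega, native, mutant, applicable,
                               flagged):
        d = Dihedrals(phi=-65.0, psi=145.0, omega=omega)
        r = rama.assess_cis_proline(d, native, mutant)
        assert r.applicable == applicable
        assert r.flagged == flagged
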