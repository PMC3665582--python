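import numpy as np
import pandas as pd
import pytest

from structmut import analyses as an
from structmut import fixtures as fx
from structmut.structure_model import MutationSpec, NativeMismatchError, read_pdb
from structmut import report as rpt


class TestInterfaceAndBinding:
    def test_single_chain_score_zero(self, helix_structure):
        r = an.analyze_interface(helix_structure, ("A", 5))
        assert r.applicable and not r.flagged and r.score == 0.0

    def test_contact_residue_flagged(self, tmp_path):
        info = fx.make_interface_fixture(tmp_path / "i.pdb")
        s = read_pdb(info["path"])
        r = an.analyze_interface(s, (info["chain"], info["seq_num"]))
        assert r.flagged and r.score > 10.0
        rb = an.analyze_binding(s, (info["chain"], info["seq_num"]))
        assert rb.flagged and rb.score >= 1

    def test_far_side_residue_unflagged(self, tmp_path):
        info = fx.make_interface_fixture(tmp_path / "i2.pdb")
        s = read_pdb(info["path"])
        far = max(s.chains["A"], key=lambda res: min(
            np.linalg.norm(b.coords - res.atom("CA").coords)
            for bres in s.chains["B"] for b in bres.atoms))
        r = an.analyze_interface(s, far.id)
        assert not r.flagged
        assert not an.analyze_binding(s, far.id).flagged


class TestSprotft:
    TABLE = pd.DataFrame({
        "accession": ["P1", "P1", "P2"],
        "position": [7, 7, 7],
        "feature_type": ["ACT_SITE", "BINDING", "MOD_RES"],
    })

    def test_matching_rows_flag_and_count(self):
        mut = MutationSpec("P1", "A", 7, "G", "R")
        r = an.analyze_sprotft(self.TABLE, mut)
        assert r.flagged and r.score == 2.0

    def test_no_table_not_applicable(self):
        mut = MutationSpec("P1", "A", 7, "G", "R")
        assert not an.analyze_sprotft(None, mut).applicable

    def test_position_without_feature(self):
        mut = MutationSpec("P1", "A", 8, "G", "R")
        r = an.analyze_sprotft(self.TABLE, mut)
        assert r.applicable and not r.flagged and r.score == 0.0


class TestVoid:
    def test_solid_control_scores_zero(self, tmp_path):
        info = fx.make_void_fixture(tmp_path / "solid.pdb", solid=True)
        s = read_pdb(info["path"])
        r = an.analyze_void(s, ("A", 1), "G")
        assert r.score == 0.0 and not r.flagged

    @pytest.mark.parametrize("radius,should_flag", [(3.0, False), (5.0, True)])
    def test_sphere_cavity_volume(self, tmp_path, radius, should_flag):
        info = fx.make_void_fixture(tmp_path / f"v{radius}.pdb",
                                    inner_radius=radius)
        s = read_pdb(info["path"])
        r = an.analyze_void(s, ("A", 1), "G")
        expected = info["expected_volume"]
        assert r.score == pytest.approx(expected, rel=0.15)
        assert r.flagged == should_flag


class TestHbond:
    def test_lost_hydroxyl_bond_flagged(self, tmp_path):
        info = fx.make_hbond_fixture(tmp_path / "h.pdb")
        s = read_pdb(info["path"])
        r = an.analyze_hbond(s, ("A", 1), "A")
        assert r.flagged and r.score == 1.0

    def test_equivalent_atom_retains_bond(self, tmp_path):
        info = fx.make_hbond_fixture(tmp_path / "h2.pdb")
        s = read_pdb(info["path"])
        r = an.analyze_hbond(s, ("A", 1), "T")  # Ser OG -> Thr OG1
        assert not r.flagged and r.score == 0.0
        assert r.extras["n_bonds_native"] == 1.0

    def test_apolar_native_scores_zero(self, helix_structure):
        r = an.analyze_hbond(helix_structure, ("A", 5), "S")
        assert r.score == 0.0


class TestPolarityRules:
    def test_buried_philic_introduction_flagged(self, cage_structure):
        r = an.analyze_corephilic(cage_structure, ("A", 1), "D")
        assert r.flagged

    def test_exposed_phobic_introduction_flagged(self, tmp_path):
        s = read_pdb(fx.make_helix(5, tmp_path / "d.pdb", sequence="AADAA"))
        assert an.analyze_surfacephobic(s, ("A", 3), "L").flagged
        assert not an.analyze_corephilic(s, ("A", 3), "L").flagged

    def test_same_class_substitution_never_flagged(self, cage_structure,
                                                   helix_structure):
        assert not an.analyze_corephilic(cage_structure, ("A", 1), "I").flagged
        assert not an.analyze_surfacephobic(helix_structure, ("A", 5), "G").flagged

    def test_score_is_hydropathy_difference(self, helix_structure):
        r = an.analyze_surfacephobic(helix_structure, ("A", 5), "I")
        assert r.score == pytest.approx(4.5 - 1.8)


class TestBuriedCharge:
    def test_new_unpaired_buried_charge_flagged(self, cage_structure):
        r = an.analyze_buriedcharge(cage_structure, ("A", 1), "K")
        assert r.flagged

    def test_countercharge_satisfies(self, tmp_path):
        info = fx.make_cage_fixture(tmp_path / "c.pdb",
                                    countercharge_distance=3.2)
        s = read_pdb(info["path"])
        r = an.analyze_buriedcharge(s, ("A", 1), "K")
        assert not r.flagged
        assert r.score == pytest.approx(3.2, abs=0.05)

    def test_surface_charge_not_flagged(self, helix_structure):
        assert not an.analyze_buriedcharge(helix_structure, ("A", 5), "K").flagged


class TestSSGeometry:
    def test_bonded_pair_broken_by_mutation(self, tmp_path):
        info = fx.make_ss_fixture(tmp_path / "ss.pdb")
        s = read_pdb(info["path"])
        r = an.analyze_ssgeometry(s, ("A", 1), "S")
        assert r.flagged
        assert r.score == pytest.approx(2.05, abs=0.01)

    def test_free_cysteine_not_flagged(self, tmp_path):
        s = read_pdb(fx.make_helix(9, tmp_path / "fc.pdb",
                                   sequence="CAAAAAAAC"))
        r = an.analyze_ssgeometry(s, ("A", 1), "S")
        assert r.applicable and not r.flagged and r.score > 2.5

    def test_non_cys_not_applicable(self, helix_structure):
        assert not an.analyze_ssgeometry(helix_structure, ("A", 5), "C").applicable


class TestImpact:
    def test_invariant_column(self):
        r = an.analyze_impact(["AAAA"] * 30, 2, "A", "G")
        assert r.score == pytest.approx(1.0) and r.flagged

    def test_uniform_column_scores_zero(self):
        seqs = [aa * 3 for aa in "ACDEFGHIKLMNPQRSTVWY"]
        r = an.analyze_impact(seqs, 1, "A", "G")
        assert r.score == pytest.approx(0.0, abs=1e-12)
        assert not r.flagged

    def test_ninety_ten_column_matches_entropy_formula(self):
        msa = ["GGG"] * 90 + ["AAA"] * 10
        r = an.analyze_impact(msa, 1, "G", "A")
        p = np.array([0.9, 0.1])
        expected = 1.0 + (p * np.log(p)).sum() / np.log(20.0)
        assert r.score == pytest.approx(expected, abs=1e-12)


class TestRunAll:
    def test_fourteen_results_and_or_semantics(self, tmp_path, rama_maps):
        s = read_pdb(fx.make_helix(7, tmp_path / "r.pdb", sequence="AAAGAAA"))
        rep = an.run_all(s, MutationSpec("r", "A", 4, "G", "R"),
                         maps=rama_maps)
        assert len(rep.results) == 14
        assert rep.explained == any(r.flagged for r in rep.results)

    def test_clash_only_flag_explains(self, tmp_path, rama_maps):
        info = fx.make_clash_fixture([1.0, 1.0], tmp_path / "cl.pdb")
        s = read_pdb(info["path"])
        rep = an.run_all(s, MutationSpec("cl", info["chain"],
                                         info["seq_num"], info["native"],
                                         info["mutant"]), maps=rama_maps)
        assert rep.result("clash").flagged
        assert rep.explained

    def test_all_negative_not_explained(self, tmp_path, rama_maps):
        s = read_pdb(fx.make_helix(7, tmp_path / "n.pdb"))
        rep = an.run_all(s, MutationSpec("n", "A", 4, "A", "G"),
                         maps=rama_maps)
        assert not rep.explained

    def test_native_mismatch_hard_error(self, helix_structure, rama_maps):
        with pytest.raises(NativeMismatchError):
            an.run_all(helix_structure, MutationSpec("x", "A", 5, "G", "R"),
                       maps=rama_maps)

    def test_reports_are_deterministic(self, tmp_path, rama_maps):
        s = read_pdb(fx.make_helix(7, tmp_path / "det.pdb",
                                   sequence="AAAGAAA"))
        mut = MutationSpec("det", "A", 4, "G", "R")
        j1 = rpt.report_json(an.run_all(s, mut, maps=rama_maps))
        j2 = rpt.report_json(an.run_all(s, mut, maps=rama_maps))
        assert j1 == j2

    def test_flag_score_threshold_consistency(self, tmp_path, rama_maps):
        """For every threshold-based analysis the Boolean call equals
        the continuous score compared with the configured cutoff."""
        info = fx.make_clash_fixture([1.0, 1.0], tmp_path / "fc.pdb")
        s = read_pdb(info["path"])
        rep = an.run_all(s, MutationSpec("fc", "A", 1, "A", "I"),
                         maps=rama_maps)
        model = rpt.build_report(rep)
        greater_is_bad = {"interface", "clash", "void", "glycine", "proline"}
        for entry in model.detail:
            if not entry.applicable or entry.threshold is None:
                continue
            if entry.analysis in greater_is_bad:
                assert entry.flagged == (entry.score > entry.threshold)
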