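import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from structmut import fixtures as fx
from structmut import predictor as pred
from structmut.analyses import run_all
from structmut.structure_model import MutationSpec, read_pdb


@pytest.fixture(scope="module")
def helix_report(tmp_path_factory, rama_maps):
    tmp = tmp_path_factory.mktemp("rep")
    s = read_pdb(fx.make_helix(7, tmp / "h.pdb", sequence="AAAGAAA"))
    return run_all(s, MutationSpec("h", "A", 4, "G", "R"), maps=rama_maps)


class TestFeatureExtraction:
    def test_vector_has_47_entries(self, helix_report):
        assert pred.extract_features(helix_report).shape == (47,)
        assert len(pred.FEATURE_NAMES) == 47

    def test_flags_and_scores_pass_through(self, helix_report):
        vec = dict(zip(pred.FEATURE_NAMES,
                       pred.extract_features(helix_report)))
        clash = helix_report.result("clash")
        assert vec["clash_flag"] == float(clash.flagged)
        assert vec["clash_total_energy"] == pytest.approx(clash.score)
        assert vec["rama_available"] == 1.0
        assert vec["volume_delta"] == pytest.approx(173.4 - 60.1)  # G->R

    def test_unflagged_report_has_zero_flag_features(self, tmp_path_factory,
                                                     rama_maps):
        tmp = tmp_path_factory.mktemp("neg")
        s = read_pdb(fx.make_helix(7, tmp / "n.pdb"))
        rep = run_all(s, MutationSpec("n", "A", 4, "A", "G"), maps=rama_maps)
        vec = dict(zip(pred.FEATURE_NAMES, pred.extract_features(rep)))
        for name in pred.FEATURE_NAMES[:14]:
            assert vec[name] == 0.0

    def test_features_frame_carries_grouping(self, helix_report):
        df = pred.features_frame([helix_report], labels=["PD"])
        assert df.shape[0] == 1
        assert set(pred.FEATURE_NAMES) <= set(df.columns)
        assert df.loc[0, "mutation_key"] == helix_report.mutation.mutation_key


class TestGroupedFolds:
    def test_equal_key_fold_sizes(self):
        df = fx.synth_mutation_dataset(100, seed=0)
        folds = pred.grouped_folds(df, k=10, seed=1)
        sizes = df.assign(fold=folds).groupby("fold")["mutation_key"].nunique()
        assert (sizes == 10).all()

    def test_key_rows_stay_together(self):
        df = fx.synth_mutation_dataset(40, chains_per_key=3, seed=2)
        folds = pred.grouped_folds(df, k=10, seed=3)
        per_key = df.assign(fold=folds).groupby("mutation_key")["fold"].nunique()
        assert (per_key == 1).all()

    def test_no_key_leakage_any_fold(self):
        df = fx.synth_mutation_dataset(55, chains_per_key=2, seed=4)
        folds = pred.grouped_folds(df, k=10, seed=5)
        for f in range(10):
            train = set(df.loc[folds != f, "mutation_key"])
            test = set(df.loc[folds == f, "mutation_key"])
            assert not train & test

    def test_too_few_keys_rejected(self):
        df = fx.synth_mutation_dataset(5, seed=6)
        with pytest.raises(ValueError):
            pred.grouped_folds(df, k=10)


class TestBalancedResample:
    def test_minority_kept_majority_drawn(self):
        df = fx.synth_mutation_dataset(250, seed=7, pd_fraction=0.8)
        runs = pred.balanced_resample(df, n_runs=3, seed=8)
        for run in runs:
            counts = run.groupby("label")["mutation_key"].nunique()
            assert counts["PD"] == counts["SNP"] == 50

    def test_runs_draw_different_majorities(self):
        df = fx.synth_mutation_dataset(250, seed=9, pd_fraction=0.8)
        r1, r2 = pred.balanced_resample(df, n_runs=2, seed=10)
        assert set(r1[r1.label == "PD"].mutation_key) != \
               set(r2[r2.label == "PD"].mutation_key)

    def test_balanced_input_identical_runs(self):
        df = fx.synth_mutation_dataset(60, seed=11, pd_fraction=0.5)
        r1, r2 = pred.balanced_resample(df, n_runs=2, seed=12)
        assert sorted(r1.mutation_key) == sorted(r2.mutation_key)


class TestTraining:
    def test_separable_training_accuracy(self):
        df = fx.synth_mutation_dataset(80, effect_size=3.0, seed=13)
        model = pred.train(df, trees=100, seed=14)
        preds = model.predict_labels(df[list(pred.FEATURE_NAMES)].to_numpy())
        assert (preds == df["label"].to_numpy()).mean() == 1.0

    def test_vote_fraction_in_unit_interval(self):
        df = fx.synth_mutation_dataset(60, effect_size=0.5, seed=15)
        model = pred.train(df, trees=50, seed=16)
        scores = model.vote_fraction(df[list(pred.FEATURE_NAMES)].to_numpy())
        assert np.all((scores >= 0.5 - 1e-9) & (scores <= 1.0 + 1e-9))

    def test_fixed_seed_reproducible(self):
        df = fx.synth_mutation_dataset(60, effect_size=0.5, seed=17)
        X = df[list(pred.FEATURE_NAMES)].to_numpy()
        p1 = pred.train(df, trees=50, seed=18).vote_fraction(X)
        p2 = pred.train(df, trees=50, seed=18).vote_fraction(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        df = fx.synth_mutation_dataset(30, seed=19, pd_fraction=1.0)
        with pytest.raises(ValueError):
            pred.train(df, trees=10)


class TestMetrics:
    def test_perfect_and_degenerate(self):
        y = np.array(["PD"] * 5 + ["SNP"] * 5)
        assert pred.evaluate_metrics(y, y) == {"Acc": 1.0, "MCC": 1.0}
        allpd = np.array(["PD"] * 10)
        m = pred.evaluate_metrics(y, allpd)
        assert m["Acc"] == 0.5 and m["MCC"] == 0.0

    def test_hand_counted_confusion_matrix(self):
        y = np.array(["PD"] * 50 + ["SNP"] * 50)
        p = np.array(["PD"] * 40 + ["SNP"] * 10 + ["SNP"] * 45 + ["PD"] * 5)
        m = pred.evaluate_metrics(y, p)
        assert m["Acc"] == pytest.approx(0.85)
        assert m["MCC"] == pytest.approx(1750.0 / np.sqrt(45 * 50 * 50 * 55))

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(20)
        y = rng.choice(["PD", "SNP"], 200)
        p = rng.choice(["PD", "SNP"], 200)
        mine = pred.evaluate_metrics(y, p)["MCC"]
        ref = matthews_corrcoef(y == "PD", p == "PD")
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(21)
        y = rng.choice(["PD", "SNP"], 300)
        p = rng.choice(["PD", "SNP"], 300)
        swap = {"PD": "SNP", "SNP": "PD"}
        m1 = pred.evaluate_metrics(y, p)
        m2 = pred.evaluate_metrics([swap[a] for a in y], [swap[a] for a in p])
        assert m1["MCC"] == pytest.approx(m2["MCC"], abs=1e-12)
        assert -1.0 <= m1["MCC"] <= 1.0


class TestProtocol:
    def test_separable_data_high_metrics(self):
        df = fx.synth_mutation_dataset(120, chains_per_key=2,
                                       effect_size=2.0, seed=22)
        res = pred.crossvalidate_protocol(df, k=10, n_runs=2, trees=100,
                                          seed=23)
        assert res.acc >= 0.95
        assert res.mcc >= 0.9
        assert res.acc == pytest.approx(
            np.mean([r["Acc"] for r in res.runs]))

    def test_config_echoed(self):
        df = fx.synth_mutation_dataset(60, effect_size=1.0, seed=24)
        res = pred.crossvalidate_protocol(df, k=5, n_runs=2, trees=20,
                                          features_per_tree=4, seed=25)
        assert res.config["trees"] == 20
        assert res.config["features_per_tree"] == 4
        assert res.config["seed"] == 25
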