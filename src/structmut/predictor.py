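"""Pathogenicity prediction from structural-analysis reports.

A report of the fourteen analyses is flattened to a fixed 47-feature
vector (registry below).  Training follows the balanced, structure-aware
protocol: the full minority class plus an equal-sized random draw of
majority-class mutations, repeated over several runs; within each run a
manual grouped 10-fold cross-validation keeps every chain-mapped copy of
the same mutation in a single fold, so the same mutation never appears
in both train and test sets via different PDB chains.  The classifier is
a random forest whose output is the fraction of trees voting for the
winning class.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .params import CHARGE, load_hydropathy, load_residue_volumes
from .results import ANALYSIS_NAMES, AnalysisReport
from .templates import sidechain_atom_names
from .params import ONE_TO_THREE

__all__ = [
    "FEATURE_NAMES", "REGISTRY_VERSION", "DISTANCE_SENTINEL",
    "LABELS", "FEATURES_PER_TREE_LARGE", "FEATURES_PER_TREE_SMALL",
    "extract_features", "features_frame", "grouped_folds",
    "balanced_resample", "train", "predict", "evaluate_metrics",
    "crossvalidate_protocol", "RFModel", "CVResult",
]

REGISTRY_VERSION = "1"
DISTANCE_SENTINEL = 999.0
LABELS = ("PD", "SNP")      # PD first: deterministic tie-break order
FEATURES_PER_TREE_LARGE = 40   # preset for large training sets
FEATURES_PER_TREE_SMALL = 4    # preset for small training sets

# The fixed 47-entry feature registry.  Boolean analysis outcomes come
# first (0/1 in the dispatcher's analysis order), then continuous scores
# with availability indicators where an analysis can be inapplicable
# (inapplicable -> value 0 with indicator 0).
FEATURE_NAMES: tuple = tuple(
    [f"{name}_flag" for name in ANALYSIS_NAMES] + [
        "clash_total_energy", "clash_lj_energy", "clash_torsion_energy",
        "clash_legacy_count", "clash_legacy_damaging",
        "rama_native_energy", "rama_mutant_energy", "rama_delta_energy",
        "rama_available",
        "omega", "omega_available",
        "void_volume",
        "hbonds_lost", "hbonds_native",
        "interface_dsasa",
        "binding_contacts",
        "conservation", "conservation_available",
        "sprotft_count", "sprotft_available",
        "rel_access",
        "hydropathy_native", "hydropathy_mutant", "hydropathy_delta",
        "charge_native", "charge_mutant", "charge_delta",
        "volume_native", "volume_mutant", "volume_delta",
        "ss_distance",
        "countercharge_distance",
        "sidechain_atom_delta",
    ]
)
assert len(FEATURE_NAMES) == 47


def extract_features(report: AnalysisReport) -> np.ndarray:
    """Deterministic 47-vector from one analysis report."""
    try:
        res = {name: report.result(name) for name in ANALYSIS_NAMES}
    except KeyError as exc:
        raise ValueError(f"report is missing analysis {exc}") from exc

    def score(name, default=0.0):
        r = res[name]
        return float(r.score) if (r.applicable and r.score is not None) else default

    def extra(name, key, default=0.0):
        r = res[name]
        return float(r.extras.get(key, default)) if r.applicable else default

    mut = report.mutation
    native, mutant = mut.native_aa, mut.mutant_aa
    kd = load_hydropathy()
    vol = load_residue_volumes()

    rama = res["glycine"] if res["glycine"].applicable else res["proline"]
    rama_ok = rama.applicable

    values = {f"{n}_flag": float(res[n].flagged) for n in ANALYSIS_NAMES}
    values.update({
        "clash_total_energy": score("clash"),
        "clash_lj_energy": extra("clash", "lj_energy"),
        "clash_torsion_energy": extra("clash", "torsion_energy"),
        "clash_legacy_count": extra("clash", "legacy_overlap_count"),
        "clash_legacy_damaging": extra("clash", "legacy_damaging"),
        "rama_native_energy": float(rama.extras.get("native_class_energy", 0.0)) if rama_ok else 0.0,
        "rama_mutant_energy": float(rama.extras.get("mutant_class_energy", 0.0)) if rama_ok else 0.0,
        "rama_delta_energy": float(rama.extras.get("delta_energy", 0.0)) if rama_ok else 0.0,
        "rama_available": float(rama_ok),
        "omega": extra("cisproline", "omega"),
        "omega_available": float(res["cisproline"].applicable),
        "void_volume": score("void"),
        "hbonds_lost": score("hbond"),
        "hbonds_native": extra("hbond", "n_bonds_native"),
        "interface_dsasa": score("interface"),
        "binding_contacts": score("binding"),
        "conservation": score("impact"),
        "conservation_available": float(res["impact"].applicable),
        "sprotft_count": score("sprotft"),
        "sprotft_available": float(res["sprotft"].applicable),
        "rel_access": extra("corephilic", "rel_access"),
        "hydropathy_native": kd[native][0],
        "hydropathy_mutant": kd[mutant][0],
        "hydropathy_delta": kd[mutant][0] - kd[native][0],
        "charge_native": float(CHARGE.get(native, 0)),
        "charge_mutant": float(CHARGE.get(mutant, 0)),
        "charge_delta": float(CHARGE.get(mutant, 0) - CHARGE.get(native, 0)),
        "volume_native": vol[native],
        "volume_mutant": vol[mutant],
        "volume_delta": vol[mutant] - vol[native],
        "ss_distance": score("ssgeometry", default=DISTANCE_SENTINEL),
        "countercharge_distance": score("buriedcharge",
                                        default=DISTANCE_SENTINEL),
        "sidechain_atom_delta": float(
            len(sidechain_atom_names(ONE_TO_THREE[mutant]))
            - len(sidechain_atom_names(ONE_TO_THREE[native]))),
    })
    vec = np.array([values[n] for n in FEATURE_NAMES], float)
    assert vec.shape == (47,)
    return vec


def features_frame(reports: Sequence[AnalysisReport], labels=None) -> pd.DataFrame:
    """Stack reports into a dataset frame with grouping metadata."""
    rows = []
    for i, rep in enumerate(reports):
        row = {"mutation_key": rep.mutation.mutation_key,
               "structure": rep.mutation.structure_ref,
               "chain": rep.mutation.chain_id}
        if labels is not None:
            row["label"] = labels[i]
        row.update(zip(FEATURE_NAMES, extract_features(rep)))
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------- CV machinery

def _key_labels(df: pd.DataFrame) -> pd.Series:
    per_key = df.groupby("mutation_key")["label"].nunique()
    mixed = per_key[per_key > 1]
    if len(mixed):
        raise ValueError(f"mutation keys with conflicting labels: "
                         f"{list(mixed.index)[:5]}")
    return df.groupby("mutation_key")["label"].first()


def grouped_folds(df: pd.DataFrame, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per row such that all rows sharing a mutation_key land
    in one fold and fold sizes in keys differ by at most one."""
    keys = np.array(sorted(df["mutation_key"].unique()))
    if len(keys) < k:
        raise ValueError(f"need at least {k} mutation keys, got {len(keys)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    key_fold = {key: i % k for i, key in enumerate(keys)}
    return df["mutation_key"].map(key_fold).to_numpy()


def balanced_resample(df: pd.DataFrame, n_runs: int = 10,
                      seed: int = 0) -> list:
    """Balanced datasets for the repeated-runs protocol: every run keeps
    all minority-class mutation keys and draws an equal number of
    majority-class keys without replacement."""
    key_labels = _key_labels(df)
    counts = key_labels.value_counts()
    if len(counts) != 2:
        raise ValueError(f"expected two classes, got {list(counts.index)}")
    ordered = sorted(counts.index, key=lambda lab: (counts[lab], lab))
    minority, majority = ordered[0], ordered[1]
    min_keys = key_labels[key_labels == minority].index.to_numpy()
    maj_keys = np.array(sorted(key_labels[key_labels == majority].index))
    out = []
    for sub in np.random.SeedSequence(seed).spawn(n_runs):
        rng = np.random.default_rng(sub)
        chosen = rng.choice(maj_keys, size=len(min_keys), replace=False) \
            if len(maj_keys) > len(min_keys) else maj_keys
        keep = set(min_keys) | set(chosen)
        out.append(df[df["mutation_key"].isin(keep)].reset_index(drop=True))
    return out


@dataclass
class RFModel:
    clf: RandomForestClassifier
    feature_names: tuple = FEATURE_NAMES
    registry_version: str = REGISTRY_VERSION
    config: dict = field(default_factory=dict)

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting for the winning class, per row."""
        proba = self.clf.predict_proba(np.asarray(X, float))
        return proba.max(axis=1)

    def predict_labels(self, X) -> np.ndarray:
        proba = self.clf.predict_proba(np.asarray(X, float))
        classes = list(self.clf.classes_)
        ipd = classes.index("PD")
        isnp = classes.index("SNP")
        # ties go to PD (fixed ordering)
        return np.where(proba[:, ipd] >= proba[:, isnp], "PD", "SNP")


def _matrix(df: pd.DataFrame):
    return df[list(FEATURE_NAMES)].to_numpy(float), df["label"].to_numpy()


def train(dataset: pd.DataFrame, trees: int = 1000,
          features_per_tree: Optional[int] = FEATURES_PER_TREE_SMALL,
          seed: int = 0) -> RFModel:
    """Fit the random forest on a dataset frame.

    `features_per_tree` follows the two documented presets: 40 for large
    training sets, 4 (default) for small ones.
    """
    X, y = _matrix(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    max_features = min(features_per_tree, X.shape[1]) \
        if features_per_tree else "sqrt"
    clf = RandomForestClassifier(
        n_estimators=trees, max_features=max_features,
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
        n_jobs=1,
    )
    clf.fit(X, y)
    return RFModel(clf=clf, config={
        "trees": trees, "features_per_tree": features_per_tree, "seed": seed})


def predict(model: RFModel, dataset: pd.DataFrame) -> pd.DataFrame:
    X = dataset[list(model.feature_names)].to_numpy(float)
    out = dataset[[c for c in ("mutation_key", "structure", "chain")
                   if c in dataset.columns]].copy()
    out["predicted"] = model.predict_labels(X)
    out["vote_fraction"] = model.vote_fraction(X)
    return out


def evaluate_metrics(labels, predictions) -> dict:
    """Accuracy and Matthews correlation coefficient, PD as positive.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined
    as 0 when any factor of the denominator is 0.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels/predictions length mismatch")
    tp = np.count_nonzero((y == "PD") & (p == "PD"))
    tn = np.count_nonzero((y == "SNP") & (p == "SNP"))
    fp = np.count_nonzero((y == "SNP") & (p == "PD"))
    fn = np.count_nonzero((y == "PD") & (p == "SNP"))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {"Acc": float(acc), "MCC": float(mcc)}


@dataclass
class CVResult:
    acc: float
    mcc: float
    runs: list = field(default_factory=list)   # per-run dicts
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"Acc": self.acc, "MCC": self.mcc, "runs": self.runs,
                "config": self.config}


def crossvalidate_protocol(dataset: pd.DataFrame, k: int = 10,
                           n_runs: int = 10, trees: int = 1000,
                           features_per_tree: Optional[int] = FEATURES_PER_TREE_SMALL,
                           seed: int = 0, grouped: bool = True) -> CVResult:
    """Balanced repeated runs of (grouped) k-fold cross-validation.

    Metrics are averaged over folds within a run, then over runs.  With
    `grouped` (the default) folds partition mutation keys, eliminating
    structural overlap between train and test; `grouped=False` reproduces
    naive row-level folding, for demonstrating the leakage inflation.
    """
    master = np.random.SeedSequence(seed)
    resample_seed, fold_seed, fit_seed = master.generate_state(3) % (2**31)
    balanced = balanced_resample(dataset, n_runs=n_runs, seed=int(resample_seed))
    run_results = []
    for run_idx, run_df in enumerate(balanced):
        if grouped:
            folds = grouped_folds(run_df, k=k, seed=int(fold_seed) + run_idx)
        else:
            rng = np.random.default_rng(int(fold_seed) + run_idx)
            perm = rng.permutation(len(run_df))
            folds = np.empty(len(run_df), int)
            folds[perm] = np.arange(len(run_df)) % k
        fold_metrics = []
        for fold in range(k):
            test = run_df[folds == fold]
            tr = run_df[folds != fold]
            if grouped:
                overlap = set(tr["mutation_key"]) & set(test["mutation_key"])
                assert not overlap, f"train/test key leakage: {overlap}"
            if test.empty or tr["label"].nunique() < 2:
                continue
            model = train(tr, trees=trees,
                          features_per_tree=features_per_tree,
                          seed=int(fit_seed) + 97 * run_idx + fold)
            preds = model.predict_labels(test[list(FEATURE_NAMES)].to_numpy(float))
            fold_metrics.append(evaluate_metrics(test["label"].to_numpy(), preds))
        run_results.append({
            "Acc": float(np.mean([m["Acc"] for m in fold_metrics])),
            "MCC": float(np.mean([m["MCC"] for m in fold_metrics])),
            "folds": fold_metrics,
        })
    return CVResult(
        acc=float(np.mean([r["Acc"] for r in run_results])),
        mcc=float(np.mean([r["MCC"] for r in run_results])),
        runs=run_results,
        config={"k": k, "n_runs": n_runs, "trees": trees,
                "features_per_tree": features_per_tree, "seed": seed,
                "grouped": grouped,
                "registry_version": REGISTRY_VERSION},
    )
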