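# structmut

Rule-based structural impact analysis of missense mutations on protein
structures, and a random-forest predictor of pathogenicity trained on
the analysis outputs.

Given a PDB file and a substitution (chain, residue number, native and
mutant amino acid), `structmut` runs fourteen named analyses — interface
burial, chain/ligand binding contacts, annotated functional features,
steric clash, destabilising voids, cis-proline loss, from-glycine and
to-proline backbone strain, hydrogen-bond disruption, hydrophilic
residues in the core, hydrophobic residues on the surface, unsatisfied
buried charges, disulphide disruption, and sequence conservation — each
returning a continuous score *and* a Boolean damage call. A mutation is
"explained" when any structural analysis flags it. The same outputs
feed a 47-feature random-forest classifier evaluated with a balanced,
structure-aware cross-validation protocol.

It is aimed at structural bioinformaticians who want interpretable,
per-mechanism verdicts for individual variants, plus a reference
implementation of the evaluation protocol that avoids *structural
overlap* — the same mutation mapped to several PDB chains leaking
between training and test folds.

## The two pseudo-energies at the core

**Clash.** Replacing a sidechain in a fixed environment is scored as

```
E = Σ_pairs (A/r¹² − B/r⁶) + Σ_χ k (1 + cos(n·χ + φ))
```

a 12-6 Lennard-Jones sum over every (mutant sidechain heavy atom,
environment heavy atom) pair within 8 Å, plus a torsion term per
sidechain χ expressing the preference for staggered rotamers
(A = εRmin¹², B = 2εRmin⁶, so the pair minimum is −ε at Rmin). The
mutation is called damaging above 34.33 kcal/mol (a stricter
13.4 kcal/mol 99th-percentile preset is also provided). The legacy
Boolean rule — at least three van der Waals overlaps of any depth — is
retained as a comparator: it misses deep two-atom clashes and over-calls
grazing triples, which the energy resolves.

**Backbone torsion.** Glycine and proline have atypical accessible
regions of the Ramachandran plot, so mutations from-glycine or
to-proline can demand backbone rearrangement. φ/ψ observations are
binned on a 1° grid per residue class (glycine / proline / other),
smoothed by averaging each cell with its eight toroidal neighbours,
and converted to a pseudo-energy

```
E = −log(obs / exp),   exp = N / 360²
```

with a per-map threshold set so that at most 1 % of the calibration
observations score worse. A from-glycine (to-proline) mutation is
flagged when the native backbone conformation exceeds the threshold of
the mutant's class map.

## Worked example

Build torsion maps from the synthetic calibration sampler, then analyse
a glycine in the left-handed helical region (φ = 80°, ψ = −10°, a
conformation comfortable only for glycine) mutated to alanine:

```bash
structmut make helix --n 7 --sequence AAAGAAA --out helix.pdb  # fixture
structmut rama-build --synthetic 20000 --seed 1 --out maps.npz
structmut analyze --pdb helix.pdb --chain A --resnum 4 \
    --native G --mutant A --maps maps.npz
```

`rama-build` prints the calibrated per-class thresholds:

```
glycine: n_obs=20000 threshold=0.329
proline: n_obs=20000 threshold=-0.770
other: n_obs=20000 threshold=0.329
```

and the report's glycine entry reads

```json
{
  "analysis": "glycine",
  "applicable": true,
  "flagged": true,
  "score": 0.4338645826298623,
  "units": "pseudo-energy",
  "detail": "other-map energy 0.43 at (phi=80.0, psi=-10.0); threshold 0.33",
  "threshold": 0.328504066972033,
  "threshold_source": "calibrated"
}
```

The mutated position scores 0.43 in the 'other' map — worse than the
0.33 threshold, because non-glycine residues essentially never adopt
φ = +80° — so the mutation is flagged and the summary block reports
`"explained": true`. The full JSON carries all fourteen analyses with
scores, units, thresholds and the provenance of each threshold
(`calibrated` vs `default`); the schema ships in
`src/structmut/data/report.schema.json`.

Training and evaluation use the same CLI:

```bash
structmut make dataset --keys 200 --effect-size 1.0 --out data.csv
structmut xval --data data.csv --runs 10 --trees 1000 --seed 0 --out cv.json
structmut train --data data.csv --trees 1000 --out model.joblib
structmut predict --model model.joblib --data data.csv --out preds.csv
```

`xval` runs the balanced repeated protocol: every run keeps all
minority-class mutations plus an equal random draw of the majority
class, then performs a manual grouped 10-fold cross-validation in which
all chain-mapped copies of a mutation share a fold. Accuracy and the
Matthews correlation coefficient are averaged over folds, then runs.

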