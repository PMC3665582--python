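# Methods

This note documents the models, parameter choices, numerical details
and known limitations of `structmut`. Empirical numbers quoted here are
the ones the test suite and `scripts/acceptance.py` compute.

## Structure model

PDB files are parsed with Biopython behind `read_pdb`, which converts
the first coordinate model into a typed structure: residues are indexed
by `(chain, seq_num, insert_code)` exactly as numbered in the file (no
renumbering — callers supply PDB numbering). Waters (HOH/WAT/DOD) are
dropped; other HETATM groups are kept as ligands and act as occluders,
binding partners and clash environment. Alternate locations resolve to
the highest-occupancy conformer; on a tie the first-listed conformer
(conventionally altloc A) is kept.

Backbone torsions follow the IUPAC convention; ω of residue *i* is the
peptide-bond torsion CA(i−1)–C(i−1)–N(i)–CA(i) preceding the residue,
which is the angle relevant for cis-proline detection (cis means
|ω| ≤ 30°, the standard convention). Angles whose defining atoms are
missing (termini, incomplete residues) are `None`, never an exception.
The torsion routine agrees with Biopython's independent vector-algebra
implementation to 10⁻⁶ degrees on random configurations.

**Solvent accessibility** uses an in-package Shrake–Rupley
implementation: 960 golden-spiral test points per atom sphere, probe
radius 1.4 Å, per-element hard-sphere radii from the packaged table.
Relative accessibility divides the residue's SASA by its SASA in an
extended Gly-X-Gly tripeptide (φ = −139°, ψ = 135°) built from ideal
geometry, computed once per residue type and cached; values are clipped
to [0, 1]. A residue is "core" at relative accessibility ≤ 0.10.
Because SASA is a local measure, a residue inside a wide cavity still
reports exposed surface — burial requires occluders within roughly
`r_i + r_j + 2·probe` of its atoms, which the test fixtures respect.

**Mutant sidechains** are grafted onto the native backbone from ideal
residue templates (the chemical component dictionary bundled with
biotite): the template N/CA/C frame is superimposed by Kabsch, the
backbone atoms are pinned to the native coordinates, and each χ torsion
is driven to the native value where the native sidechain defines the
same χ, or to 180° (extended) otherwise — a deterministic, conservative
default; a rotamer library would be a natural extension. Proline's ring
torsions stay at template values, since driving one torsion of a closed
ring would break closure. An X→X "mutation" returns the native residue
verbatim, so the operation is exactly idempotent. No repacking or
minimisation of the environment is attempted.

## Clash pseudo-energy

`E = Σ A/r¹² − B/r⁶ + Σ k(1 + cos(nχ + φ))`, summed over all (mutant
sidechain heavy atom, environment heavy atom) pairs within 8 Å and over
the mutant's χ torsions. The environment is every heavy atom of other
residues plus ligands; the mutated residue's own backbone is excluded
(its geometry is unchanged by the substitution). Parameters:

- Per-element LJ table (`data/vdw_params.tsv`): Rmin/2 and ε with
  common molecular-mechanics magnitudes (C: 2.0 Å, 0.11 kcal/mol; N:
  1.85 Å, 0.20; O: 1.70 Å, 0.12; S: 2.0 Å, 0.45; …), combined by
  Lorentz–Berthelot (Rmin_ij = Rmin_i/2 + Rmin_j/2, ε_ij = √(ε_i ε_j)),
  so that A = εRmin¹², B = 2εRmin⁶ gives E(Rmin) = −ε exactly. The
  table is configurable by file path.
- Torsions (`data/torsion_params.tsv`): one generic three-fold term
  (k = 1.4 kcal/mol, n = 3, φ = 0) for sp³ χs and a two-fold term
  (k = 1.25, n = 2, φ = 180°) for planar χs (aromatic rings,
  amide/carboxylate/guanidinium planes).
- Distances below 0.1 Å are evaluated at 0.1 Å to avoid overflow and
  flagged in the contact detail. No switching function at the 8 Å
  cutoff; pair energies there are ~10⁻⁴ kcal/mol.
- Hydrogens are ignored throughout (PDB files largely lack them, and
  the legacy overlap rule is heavy-atom by heritage).

Damaging ⇔ total > 34.33 kcal/mol (default); 13.4 kcal/mol ships as the
stricter 99th-percentile preset (`config.CLASH_ENERGY_CUTOFF_STRICT`).
The legacy comparator counts environment atoms within the sum of vdW
radii of any mutant sidechain atom, depth ignored, damaging at ≥ 3.
The engineered fixtures demonstrate both disagreement directions: two
1.0 Å-deep overlaps score ≈ 91 kcal/mol (energy-damaging, legacy-clean)
while three 0.01 Å overlaps score ≈ 0.3 kcal/mol (legacy-damaging,
energy-clean).

## Backbone-torsion maps

Counts accumulate on a 360×360 grid of half-open 1° cells anchored at
−180° (an observation at exactly +180° wraps to the −180° edge).
Smoothing is the mean of each cell with its eight neighbours with
toroidal wraparound, implemented via `scipy.ndimage.uniform_filter
(mode="wrap")`; it conserves the grand total exactly. The pseudo-energy
uses the natural log (threshold semantics are base-invariant); smoothed
counts are floored at 0.1 before the log, capping empty-cell energies
at ln(10·exp). The threshold is the observation-weighted 99th
percentile: the smallest cell energy such that at most 1 % of input
observations lie in strictly worse cells. On 10⁵ continuous synthetic
draws the realised tail fraction is between 0.9 % and 1 %.

The from-glycine flag applies when the native is Gly; the score is the
energy of the native (φ, ψ) in the *mutant's* class map ('other', or
proline when mutating to Pro), flagged above that map's threshold. The
native-class energy and the difference are reported alongside in the
extras, but the flag uses mutant-class exceedance only. To-proline is
symmetric with the proline map. Redundancy and resolution filtering of
a real calibration set is an upstream curation step; the builder skips
structures whose parsed resolution is known and worse than the cutoff
(default 1.8 Å) and otherwise maps whatever it is given. Pre-proline
residues are not separated into their own class.

## The fourteen analyses

All thresholds live in one `AnalysisConfig` object. The clash energy
(34.33 kcal/mol) and the void volume (275 Å³) are calibrated values of
the method; the rest are conventional structural-biology choices, and
reports echo the provenance of each:

| parameter | default | units |
|---|---|---|
| interface ΔSASA | 10.0 | Å² |
| binding / salt-bridge contact | 4.0 | Å |
| H-bond donor–acceptor | 3.5 | Å (angle ≥ 90°) |
| disulphide SG–SG | 2.5 | Å |
| core relative accessibility | 0.10 | — |
| conservation | 0.9 | normalised score |
| cis ω | 30 | deg |
| void volume | 275 | Å³ |
| clash energy | 34.33 | kcal/mol |

Details worth recording:

- **Void**: a 1.0 Å grid in a box extending 16 Å beyond the residue.
  Points inside any atom's vdW sphere are occupied; a 1.4 Å-probe
  flood fill from the box boundary defines solvent, which is then
  dilated by the probe radius plus half a cell of discretisation slack
  so the accessible shell between the vdW and probe-expanded surfaces
  is not mistaken for cavity (a genuine void closer than ~2.3 Å to
  solvent is therefore absorbed — a deliberate conservative choice).
  Remaining free points cluster by 6-connectivity; the score is the
  largest cluster adjacent (≤ 4 Å) to the mutated residue, computed on
  the structure after the large→small replacement. Against analytic
  sphere cavities of radius 3–6 Å the estimator is within 7 %.
- **H-bonds**: heavy-atom criterion (no hydrogens): donor–acceptor
  ≤ 3.5 Å and the angle at each end between the bond axis and the
  atom's covalent neighbour ≥ 90°. Donors/acceptors come from the
  packaged per-residue table, which also assigns each polar atom a
  functional group; a bond survives the mutation when the mutant
  sidechain carries an atom of the same group (Ser OG → Thr OG1 both
  hydroxyl). The score counts bonds lost.
- **Buried charge**: flagged when a mutation either buries a new
  D/E/K/R charge with no opposite-charge atom within 4 Å, or removes
  one partner of a buried salt bridge. The score is the distance to
  the nearest countercharge, with 999 Å as the "none anywhere"
  sentinel.
- **Conservation** (impact): normalised Shannon information
  1 − H/ln 20 of the alignment column, 1 = invariant; this entropy
  score is a documented stand-in for the original pipeline's
  conservation scoring, and output metadata labels it as such.
- **Interface vs binding**: both computed from the file as given; no
  biological-unit reconstruction.
- The dispatcher validates the stated native residue against the
  structure before running (hard error), then contains any per-plugin
  failure in that plugin's result. Reports are deterministic
  byte-for-byte.

## Predictor

Reports flatten to a fixed 47-entry feature registry (version 1): the
fourteen Boolean calls, then continuous scores (clash total/LJ/torsion,
legacy count and verdict, native/mutant/Δ torsion-map energies, ω, void
volume, H-bonds lost/native, interface ΔSASA, binding contacts,
conservation, feature counts, relative accessibility, hydropathy,
formal charge and residue volume for native/mutant/Δ, SG and
countercharge distances, sidechain atom-count change) with availability
indicators where an analysis can be inapplicable. Inapplicable values
encode as 0 with indicator 0 (distances use the 999 sentinel); nothing
is silently dropped. The exact composition of a feature set is a design
choice; this registry is versioned and recorded in model/CV metadata.

The classifier is a scikit-learn random forest, 1000 trees by default,
with `features_per_tree` presets of 40 (large training sets) and 4
(small ones, the default here). The reported score is the fraction of
trees voting for the winning class; vote ties resolve to PD (fixed
ordering) for determinism. Evaluation follows the balanced repeated
protocol: each run keeps every minority-class mutation key and an
equal-sized seeded draw of majority keys (without replacement, at key
level); within a run a manual grouped 10-fold cross-validation
partitions mutation keys — all chain-mapped rows of a key share a fold,
and the implementation asserts train/test key disjointness on every
fold. Acc and MCC (= (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
0 when a denominator factor vanishes) are averaged over folds, then
runs. One master seed derives every sub-seed.

## Synthetic data

The generators produce *minimal* scenes that satisfy each analysis'
geometric premise by construction: ideal helices (φ = −57°, ψ = −47°,
Engh–Huber-style backbone internal coordinates), single-residue clash
scenes with environment atoms at prescribed overlap depths, a
Ser···O=C hydrogen bond at 2.9 Å, an SG–SG pair at 2.05 Å, hollow and
solid carbon shells for the void estimator, a two-helix interface, and
a carbon cage for full burial. Torsion-map calibration draws come from
wrapped-Gaussian basins per residue class (helix and sheet basins for
'other'; mirrored left-handed and extended basins for glycine; φ
clamped near −65° for proline).

The labelled feature datasets give each mutation key a base
47-vector; deleterious keys are shifted by the effect size on twelve
informative features, and three feature pairs carry class signal in
their within-class correlation only (correlated in deleterious,
anti-correlated in neutral, no marginal shift) — mimicking conjunctive
structural effects such as burial × hydrophilicity. Rows replicate the
key across chains with small jitter (default σ = 0.1), emulating one
mutation observed on several PDB chains.

What this does *not* emulate: real feature marginals and their heavy
tails, correlations induced by shared protein context, label noise, or
class imbalance structure beyond a single fraction. Passing tests
therefore demonstrate the correctness of the machinery (geometry,
calibration, leakage control, protocol arithmetic), not real-data
predictive performance, which requires external curated variant sets
and structure mappings that are out of scope here.

## Problem sizes and experiment conditions

Chosen as the package's own desk-scale defaults: torsion-map
calibration at 10⁵ draws per class (tests reuse a 2×10⁴ set);
separable-protocol checks at 120 keys × 2 chains with 100 trees over 3
runs; the null check on 2,000 label-permuted rows; the leakage
demonstration at 150 keys × 3 chains with a weak (0.3) effect — grouped
CV stays near 0.57 while naive row-level CV inflates to ≈ 0.99; the
learning curve at 500 / 2,000 / 10,000 rows under the same weak-signal
condition (chosen so the smallest size is visibly data-starved rather
than saturated), rising from ≈ 0.59 to ≈ 0.66.

## Known limitations

- No environment relaxation: a clash that a real structure would
  relieve by small rearrangements is scored at face value; the energy
  cutoff is calibrated with that convention.
- Generic per-element LJ and torsion parameters, not a versioned
  forcefield; values are configurable but the defaults are magnitudes,
  not a citation-exact parameter set.
- SASA burial is local (see above); fully enclosed but wide cavities
  read as exposed.
- The conservation score is an entropy stand-in; no weighting for
  sequence redundancy or similarity matrices.
- Significance stars in the two-cohort category comparison use
  two-sided Fisher's exact tests, labelled in the output.
- Analyses run on the deposited file as given — no quaternary-assembly
  reconstruction or UniProt→PDB mapping.
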