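# Methods

This note documents the models, defaults and numerical choices behind
`peptidestack`, and what the synthetic-data experiments do and do not
demonstrate.

## Problem setting

Binary classification of short peptides (sequences over the 20 standard
amino acids) into an active and an inactive class, plus ranking of
unlabeled candidates ("virtual screening"). Non-standard residue codes
(B, J, O, U, X, Z) are rejected by default because every encoder assumes
the 20-letter alphabet; a lenient mode drops such records with a warning.
Exact-sequence duplicates are removed before training (first occurrence
kept); a sequence occurring with both labels is removed entirely, since
keeping either copy would silently pick a side. Train/test splitting is
per-class (stratified) with an explicit seed; within each class the
training share is the nearest integer to `n_class x fraction`.

## Feature encodings

**AAC / DPC.** Residue and overlapping-dipeptide frequencies; both are
probability vectors (non-negative, sum 1). Feature order is alphabetical
(A..Y; AA, AC, .., YY) for reproducible column naming.

**DDE.** For each dipeptide *ab*: observed frequency `DC`, theoretical
mean `TM = (C_a/61)(C_b/61)` from standard-genetic-code codon counts (61
sense codons), variance `TV = TM(1-TM)/(L-1)`, and
`DDE = (DC - TM)/sqrt(TV)`. An absent dipeptide is strictly negative
because `TM > 0`.

**PAAC / APAAC.** Chou's pseudo amino acid composition family. Three
per-residue scales (hydrophobicity, hydrophilicity, side-chain mass;
shipped as `data/paac_scales.tsv`) are z-scored over the 20 residues with
the population standard deviation. PAAC's correlation factor θ_j averages
the mean squared scale difference over residue pairs at distance j; APAAC
keeps per-scale products (τ terms), which can be negative because the
normalized scales have zero mean. Defaults λ=1 (fixed by the declared
dimensions 21 and 22) and weight w=0.05 (the conventional default of this
descriptor family). λ=0 is allowed and reduces both encoders exactly to
AAC, which the tests exercise as a limit identity.

**PCP.** Per-sequence means of 11 physicochemical scales
(`data/pcp_scales.tsv`: Kyte-Doolittle hydrophobicity, Hopp-Woods
hydrophilicity, side-chain mass, residue volume, Grantham polarity,
Charton polarizability, isoelectric point, net charge index, Chou-Fasman
helix and sheet propensities, Bhaskaran-Ponnuswamy flexibility). The
contract is "11 per-residue scales averaged over the sequence"; the table
is replaceable by any user file with the same layout.

**Sequence → SMILES.** Linear peptides are built from per-residue backbone
fragments `N[C@@H](side chain)C(=O)` joined directly (amide bonds), with a
free N-terminal amine and C-terminal carboxylic acid. Residues are emitted
as L-amino acids (alpha carbons 2S; threonine 3R, isoleucine 3S; cysteine
is CIP-R purely by sulfur priority); a flag strips stereo annotations,
since all four fingerprint families are substructure-based and largely
stereo-insensitive. The construction satisfies the mass balance
`MW(peptide) = Σ MW(free residue) - (L-1) x 18.01528 Da` to < 0.01 Da,
which the tests verify against an independent RDKit computation.

**Fingerprints.** All four are keyed (dictionary) fingerprints — no
hashing or folding, each bit a named feature:

- *Estate* (79): RDKit's electrotopological-state atom types, binarized to
  presence/absence.
- *MACCS* (166): RDKit MACCS keys; the toolkit emits 167 bits with bit 0
  permanently unset, which is dropped.
- *FP4* (307): Open Babel's functional-group SMARTS dictionary, computed by
  the `obabel` CLI in one batch call per dataset and decoded from its
  512-bit hex dump (patterns occupy bits 0–306). The pattern definitions
  belong to Open Babel and are not copied into this package, so FP4 feature
  names are positional.
- *PubChem-style* (881): a keyed dictionary original to this package with
  the same dimension and section structure as the public PubChem
  fingerprint — hierarchical element counts (23 elements x 5 thresholds),
  ring counts (sizes 3–10 x 7 ring characters x 2 thresholds), and 654
  SMARTS patterns (systematic bonded pairs/triples/quadruples over C/N/O/S,
  atom environments, hydrogen counts, charges, peptide-relevant functional
  groups). It is **not** bit-compatible with CACTVS PubChem fingerprints;
  the definitions live in `chem/data/pubchem_style_keys_synthetic.tsv`
  (regenerable by `scripts/generate_pubchem_style_keys.py`) so the
  dimension and bit semantics are guaranteed and auditable.

## Baseline learners and tuning

Thirteen algorithms; nine carry one-parameter grids (tree counts
{20,50,100,200,500} for AdaBoost/extra trees/LightGBM/random
forest/XGBoost, hidden-layer width {20,50,100,200,500} for the MLP, cost
{0.001..100} for logistic regression, cost 2^0..2^5 for the linear SVM and
2^-4..2^4 for the RBF SVM with the library's "scale" gamma). The untuned
four use fixed defaults: decision tree (library defaults), k-NN with k=5,
Gaussian naive Bayes, PLS with 2 components. Tuning runs stratified k-fold
CV per grid point (k capped by the minority-class count), scores pooled
out-of-fold confidences by MCC, breaks ties toward the first (smallest)
grid value, and refits the winner on all data. Stochastic learners are
seeded at construction, so tuning and prediction are reproducible given
(X, y, k, seed).

Confidences: `predict_proba[:,1]` where available; SVMs use Platt-style
calibration fitted on internal CV (`probability=True`); the PLS classifier
clips its predicted response to [0,1]. The PLS classifier also drops
zero-variance feature columns at fit time and falls back to predicting the
training base rate when none remain — this makes degenerate feature masks
score MCC 0 instead of crashing the GA's fitness evaluation.

## Stacking

The architecture is the cross-product of an ordered encoder list and an
ordered algorithm list (10 x 13 = 130 baselines by default), with columns
named `<ALGORITHM>-<ENCODER>`. The training PFV fixes one stratified
k-fold partition (default k=10) shared by all baselines; within each fold
the learner is re-tuned on the in-fold data only, so hyperparameter
selection cannot leak across the fold boundary, and its confidence fills
the held-out rows. External data is scored by baselines tuned and refitted
on the full training set, with identical column order. The meta-model is a
PLS classifier on the (optionally GA-selected) PFV columns; its component
count is chosen from {1..min(8, m)} by stratified CV MCC when not given,
and its decision threshold is fixed at 0.5 (ties to the positive class).

## GA feature selection

Chromosomes hold a binary mask over feature columns plus one parametric
gene (PLS component count in {1..8}). Defaults: population 50, per-gene
mutation probability 0.05, selected count bounded in [5, 20], tournament
size 3, uniform crossover, elitism 1, generation budget 100 with a
20-generation stagnation stop. Out-of-bounds masks are repaired by random
bit flips toward the nearer bound. Fitness is stratified k-fold CV MCC
(default k=10) of the PLS evaluator on the masked columns, computed on one
fold partition shared by all chromosomes in a run (fair comparison, and it
makes the fitness cache keyed by (mask, components) exact). Ties are
broken toward fewer selected features, then lexicographically. Elitism
makes the best-fitness history non-decreasing by construction; the
recovery experiments check the sharper claim that the final best strictly
improves on the initial population in most seeds. The operator suite is a
conventional GA configuration chosen and fixed here; every setting is
recorded in run manifests.

## Evaluation

ACC, BACC = (Sn+Sp)/2, Sn, Sp, MCC and AUC from a confusion matrix at
threshold 0.5 plus the Mann-Whitney rank statistic with midranks for ties
(so a constant predictor scores AUC exactly 0.5). Zero-denominator cases
(MCC, Sn, Sp) score 0 by convention, documented so degenerate models rank
poorly rather than erroring. Cross-validation pools out-of-fold
predictions into one report by default ("pooled"); per-fold averaging is
available ("averaged") since the choice is a genuine convention fork.

## Synthetic data

`synthetic.generate` draws residues i.i.d. from class-specific
distributions: negatives uniform over the 20 residues; positives a convex
blend `(1-s) x uniform + s x enriched`, where the enrichment map boosts
C/Y/R/F/W/M (x3 or x2) and depletes D/L/P (x0.3) — the compositional
signature typical of the bioactive class this design targets. Lengths are
uniform on [5, 25] by default, within the 3–20-residue description of the
target peptides and the 10–57 screening window. At s=0 the classes are
identically distributed (the null case); detectability is monotone in s,
which the tests check via an AAC + logistic-regression probe. An optional
first-order Markov mode adds dipeptide structure for order-sensitive
encoders. `generate_planted_pfv` emulates a stacked-confidence matrix:
Uniform(0,1) noise columns with a chosen number of columns shifted by
±shift with the label, for feature-selection recovery experiments.

What passing these tests shows: the pipeline extracts exactly the kind of
signal it is built for (compositional class differences), does not extract
signal that is not there (permutation nulls, out-of-fold leakage bounds),
and the GA finds planted informative columns among noise. What they do not
show: performance on real peptide data, where signal is weaker, classes
are imbalanced, sequences are phylogenetically correlated, and activity
depends on structure beyond composition.

## Study sizes and numerical choices

The statistical experiments use a reduced architecture — encoders (AAC,
PCP, DPC) x learners (LR, NB, DT, KNN), inner tuning folds 5 — and 200–300
samples with 5 seeds and median aggregation. These sizes were chosen as
the smallest study in which the checked effects (leakage bounds, GA
recovery, stacking dominance) are stable across seeds; the full 130-model
architecture is exercised structurally (cardinality, naming, dimensions)
and by the same code paths. Other conventions: probability/confidence
comparisons use `>=` at thresholds (ties positive); grid ties take the
smaller parameter; GA fitness ties take the smaller mask; all fold
partitions are stratified and seeded; seeds derived for the acceptance
script stay below 2^31.

## Known limitations

- Only linear, unmodified peptides; no cyclic peptides, no post-
  translational modifications, no terminal capping.
- The PubChem-style fingerprint is dimensionally and semantically faithful
  but not bit-compatible with CACTVS PubChem fingerprints.
- FP4 requires the external `obabel` executable.
- No probability calibration of the meta output and no confidence
  intervals on metrics.
- The i.i.d. synthetic generator cannot probe positional or motif-based
  signal (the Markov option adds only first-order structure).
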