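# peptidestack

Stacked-ensemble binary classification of peptide bioactivity from sequence
alone, with a virtual-screening workflow for ranking candidate peptides.

Short bioactive peptides (for example tyrosinase-inhibitory peptides, the
kind of skin-pigmentation modulators this design targets) are expensive to
verify experimentally, so a sequence-based classifier that ranks candidates
before the bench work matters. A single feature encoding rarely captures
everything that separates active from inactive peptides; `peptidestack`
therefore combines many complementary views of each sequence and lets a
second-level model learn which views to trust.

## The method

1. **Heterogeneous encodings.** Each peptide is encoded ten ways: amino
   acid composition (AAC, 20-D), dipeptide composition (DPC, 400-D),
   dipeptide deviation from expected mean (DDE, 400-D, standardized against
   a codon-usage null), pseudo and amphiphilic pseudo amino acid
   composition (PAAC 20+λ, APAAC 20+2λ, default λ=1), physicochemical
   property means (PCP, 11-D), and four keyed substructure fingerprints
   computed on the peptide's chemical structure after deterministic
   sequence→SMILES conversion: Estate (79), FP4 (307), MACCS (166) and a
   PubChem-style dictionary (881).
2. **Baseline model zoo.** Every encoding is crossed with 13 learning
   algorithms (AdaBoost, decision tree, extra trees, k-NN, LightGBM,
   logistic regression, MLP, naive Bayes, PLS, random forest, linear and
   RBF SVM, XGBoost) — 130 baseline models by default. Nine algorithms are
   grid-tuned by stratified cross-validated Matthews correlation (MCC).
3. **Probabilistic-feature stacking.** Each baseline contributes one
   *probabilistic feature* (PF): its predicted positive-class confidence.
   For training data these are produced **out-of-fold** on a single shared
   stratified k-fold partition, so no baseline ever scores a sample it was
   trained on. The resulting samples × 130 matrix is the probabilistic
   feature vector (PFV).
4. **GA feature selection.** A genetic algorithm (population 50, per-gene
   mutation 0.05, selected-feature count bounded in [5, 20], fitness =
   cross-validated MCC of a PLS classifier on the masked columns) picks the
   informative PFs and the PLS component count.
5. **PLS meta-classifier.** Partial-least-squares regression on the
   selected PFs, response clipped to [0,1], decision threshold 0.5.
   Screening ranks unlabeled peptides by this confidence after a length
   filter (default 10–57 residues) and deduplication.

Models are evaluated by ACC, BACC = (Sn+Sp)/2, Sn, Sp, MCC and AUC under
10-fold cross-validation (pooled out-of-fold predictions) and independent
tests.

## Worked example

```python
from peptidestack.synthetic import SynthConfig, generate
from peptidestack.stacking import StackingArchitecture, build_training_pfv, fit_meta
from peptidestack.evaluation import score

ds = generate(SynthConfig(n_pos=150, n_neg=150, signal=1.0, seed=11))
arch = StackingArchitecture(("AAC", "PCP", "DPC"), ("LR", "NB", "DT", "KNN"))
pfv = build_training_pfv(arch, ds, k=10, seed=11, tune_folds=5)
meta = fit_meta(pfv, ds.y, k=10, seed=11)
conf, cls = meta.predict(pfv)
print(score(ds.y, conf).to_row())
```

```
        ACC      BACC    Sn        Sp       MCC       AUC
0  0.873333  0.873333  0.86  0.886667  0.746932  0.933089
```

The synthetic task plants a compositional class difference (positives
enriched in C/Y/R/F/W/M, depleted in D/L/P), so a 12-baseline stack
separates it well. The baseline confidences are out-of-fold but the
meta-model is scored on the PFV it was fitted to, so these numbers are
mildly optimistic — use
`peptidestack.evaluation.cross_validate` or the acceptance script for
honest out-of-sample numbers.

The same workflow is available from the shell:

```bash
peptidestack synth --n-pos 150 --n-neg 150 --seed 11 --out data/demo
peptidestack train --pos pos.fasta --neg neg.fasta --out model/
peptidestack screen candidates.fasta --bundle model/ --out ranked.tsv
```

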