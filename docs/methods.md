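# Methods

## Problem setting

Given a table of IC50 measurements against a single protein target, the
package builds a binary activity classifier from SMILES alone. Activity is
defined by potency thresholds: **active** if IC50 ≤ 1 µM, **inactive** if
IC50 ≥ 10 µM. The open interval between the thresholds is deliberately
unlabeled — those compounds are excluded from modeling (and counted in the
filter log) because their class membership is ambiguous at the stated
cutoffs. Thresholds are configurable; the defaults are hard-coded as
1000 nM / 10000 nM with nM as the internal canonical unit.

## Curation

Rows are filtered in a fixed order, each step appending
(name, removed, remaining) to an auditable log: keep exact measurements
(standard relation `=`) only; drop missing SMILES/values; reject unknown
units (accepted: nM, µM); convert to nM; standardize structures (largest
organic fragment, canonical tautomer); collapse replicates.

Replicate handling: multiple `=` measurements for one compound id are
aggregated by the **geometric mean** of IC50 (arithmetic mean in pIC50
space), the conventional potency average. A compound whose replicate pIC50
standard deviation exceeds 2 is treated as irreproducible and dropped.
The "2 log-units" reproducibility bound is one defensible reading of common
curation practice and is exposed as `replicate_pic50_sd_max`; other
readings (e.g. a fixed assay-noise cutoff) can be configured.

The train/test split is stratified by class only, with per-class training
size `round(train_fraction × class size)`; membership is a pure function of
the seed (default 42, always recorded).

Chemical-space reporting covers eight descriptors — MW (Da), ALogP
(Wildman–Crippen atom-contribution logP, the toolkit's estimator of the
octanol–water partition coefficient), H-bond acceptors/donors, aromatic
bond ratio, ring count, rotatable bonds, benzene-ring count — with
per-class min/max/median/mean/SD, rule-of-five flags (MW < 500, ALogP < 5,
nHAcc < 10, nHDon < 5), and two-sided Mann–Whitney p-values per descriptor.

## Fingerprints

Twelve families at fixed published lengths (AP2D 780, CKD/CKDExt/CKDGraph
1024, Circle 1024, EState 79, Hybrid 1024, KR 4860, MACCS 166, PubChem 881,
FP4/FP4C 307). Families divide into:

* **hashed** (AP2D, CKD, CKDExt, CKDGraph, Circle, Hybrid): toolkit-native
  analogues — hashed atom pairs, linear/branched/bond-order-blind path
  fingerprints (depth 8), circular (Morgan r=2) and pharmacophoric-invariant
  circular fingerprints — folded to the published lengths with fixed,
  recorded hash parameters. These are *analogues*, not bit-for-bit clones
  of any external tool's output; the import path accepts exact matrices in
  the PADEL CSV dialect (first column = molecule name).
* **keyed** (MACCS, EState, FP4/FP4C, PubChem, KR): every feature has a
  name and a definition. MACCS and E-state atom types come from the
  toolkit. FP4/FP4C use the OpenBabel functional-group SMARTS dictionary
  (307 patterns) resolved at run time (`QSARSTACK_FP4_FILE` overrides the
  location). The PubChem-style family is a generated 881-feature dictionary
  in the same spirit as the original sections: element-count thresholds,
  ring-count/variant bits, a curated functional-group SMARTS list (cyano,
  aryl halides, amines, amides, sulfonamides, …) and enumerated
  element-pair/triple connectivity patterns. The KR-style family is a
  deterministic enumeration of 4860 linear-fragment SMARTS over a
  chemically constrained atom/bond alphabet.

Featurization is deterministic and invariant to SMILES atom renumbering
(everything goes through the parsed molecule). A binary family's bits are
monotone in substructure content; FP4 is exactly `FP4C ≥ 1`.

## Phase 1: the baseline zoo

One classifier per (algorithm, family) pair; 13 × 12 = 156 at full scale.
Hyperparameters maximize pooled (micro) cross-validated MCC over seeded
stratified folds *shared by every baseline*; ties go to the earlier grid
point in declared order. Default grids are compact and config-overridable
(trees {100, 500}, depth {None, 8}, SVM C {0.1, 1, 10}, k-NN k {3, 5, 7},
PLS components {2, 5, 10}, …); a one-point `FAST_GRIDS` profile exists for
quick runs. PLS and linear SVM have no native probabilities; their decision
values pass through a one-dimensional logistic link fitted on the same
training fold.

**Probabilistic features.** Training-set PFs are out-of-fold predictions:
for each fold, every baseline is refit without that fold and scores only
the held-out compounds. This is standard stacking hygiene — refit-on-all
predictions would leak labels into the meta-features. The OOF result
carries fold provenance (`fold_of_row`, `fit_rows`) so the exclusion
property is assertable, not assumed. Test/screening PFs come from baselines
refit on the full training set. PF columns follow the canonical
algorithm-major order regardless of input dict order.

## Phase 2: the mCNN meta-model

The 156 PFs are a fixed-order 1-D single-channel sequence. One
convolutional layer, region sizes {3, 4, 5} × 100 filters (300 total),
"same" zero padding, ReLU. The stated 6-D penultimate vector admits two
readings of the pooling step, both implemented:

* `region-maxavg` (default): per region size, global max-pooling and global
  average-pooling over positions *and* filters → 2 scalars per region
  → 6-D;
* `filter-max-dense`: global max per filter → 300-D → dense layer to 6-D.

Neither is asserted to match any external implementation; the default is
the one that produces 6-D without extra parameters. The 6-D vector feeds a
softmax over {active, inactive}. Unstated training details are fixed as:
Adam, batch 32, cross-entropy, He/Glorot-style seeded initialization. The
implementation is plain NumPy (forward + backprop); training is
deterministic given the config seed. Grid search covers epochs
{20, 50, 100, 200} × learning rate {1e-5, 1e-4, 1e-3, 1e-2} by 10-fold CV
MCC; one trajectory per learning rate per fold is checkpointed at each
epoch budget (identical to independent runs, since initialization and
shuffling depend only on the seed), and a diverging grid point is scored
MCC −1 and logged. Classification threshold is 0.5 with ties classed
active. Thirteen conventional ML meta-learners over the identical PF matrix
provide comparison rows.

The 6-D bottleneck is intentionally narrow: on tiny toy problems it needs a
hot learning rate (~1e-2) to saturate, while on realistic PF matrices —
where most columns correlate with the label — the default 1e-3 converges
comfortably.

## Evaluation

Threshold metrics from confusion counts: F1, Sn, Sp, ACC, and MCC with the
standard four-factor square-root denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A denominator of zero reports the metric
as 0 with an `undefined` flag. AUC is trapezoidal ROC integration
(equivalently the normalized Mann–Whitney U; ties get half credit).
Cross-validation uses seeded stratified folds shared across compared
models; pooled (micro) confusion counts are the headline CV metrics, with
per-fold means also reported. Whether pooled or fold-averaged metrics are
"the" CV numbers is a genuinely open convention; pooled is the default here
because it weights every compound equally.

## Interpretation

Two attribution routes, kept deliberately independent:

* **Permutation Shapley** (model-agnostic, used for the mCNN): each sampled
  draw pairs a random feature permutation with a random background row and
  telescopes from background to the explained compound. Per-compound
  attributions sum *exactly* to (model output − base value) for any number
  of draws, so local accuracy is structural, not approximate; sampling only
  affects variance of the per-feature split. Defaults: 10 draws, background
  = 100 training PF rows (seeded); the background size is a convention, not
  a derived quantity.
* **Native TreeSHAP** (`pred_contrib`) for the gradient-boosting surrogate
  trained on an interpretable keyed family (default: PubChem-style), in
  log-odds space. The surrogate's ranked features are reported with SMARTS
  patterns and descriptions (top-20 by default); per-compound waterfalls
  export signed contributions ordered by magnitude with a cumulative column
  ending at the model output.

## Screening

Featurize → apply the refit zoo → meta-model probability → stable sort
descending. Compounds matching a training/test structure by canonical
SMILES are flagged and excluded before ranking (ids are unreliable across
sources). Ties keep input order; probabilities are written to 5 decimals.

## Synthetic benchmark

Molecules are assembled from five scaffolds (benzene, pyridine, indoline,
naphthalene, cyclohexane) with two decoration slots drawn from a weighted
set of common substituents, then canonicalized — real, parseable structures
that exercise the fingerprint stack genuinely. Activity is logistic in
planted motif presences. Defaults (the benchmark conditions): 433 active /
409 inactive; intercept −4; cyano +8; aryl halide +6; bulky substituents
(≥4-carbon chain, pendant phenyl) −2 each via the `mw_shift` knob; label
noise 5%. The large coefficients make the planted effects near-saturated,
so the irreducible error is dominated by the explicit noise rate — a
"strong effect" benchmark by design. The negative bulk coefficients make
actives emerge lighter on average (the MW gap is emergent, not imposed).
IC50 values are back-assigned log-uniformly within each class's threshold
region, so curation reproduces the labels losslessly.

What the generator does **not** emulate: activity cliffs, assay noise
structure, scaffold-hopping chemotypes, class imbalance beyond the config,
or realistic MW ranges (the grammar yields fragment-sized molecules,
~100–250 Da). Passing recovery tests therefore shows the pipeline's
machinery is sound — leakage-free stacking, faithful attribution of a known
mechanism — not that it will reach the same metrics on real bioactivity
data.

`recover()` locates each planted motif's feature by exact SMARTS equality
in the family dictionary, ranks features by mean |SHAP|, and calls a
feature "noise" when its absolute Pearson correlation with the noiseless
activity probability is below 0.1 across compounds — correlated proxies of
the mechanism (e.g. halogen element-count bits) are thereby not counted
against recovery.

## Numerical and design choices

* Degenerate CV folds (a class missing from a fold) are refolded once with
  a perturbed seed, then raised as an error.
* Grid-search and ranking ties break to the earlier candidate in declared
  order (stable sorts throughout).
* PF values are clipped to [0, 1] after probability extraction; the PF
  container rejects out-of-range values.
* The reduced profile (4 algorithms × 3 families, 5 folds, fast grids,
  fixed meta-config) is the default `RunConfig`; the full 13 × 12 / 10-fold
  / grid-searched profile is `RunConfig.full()`. The reduced profile is the
  problem size used by the test suite and the acceptance script.
* Determinism: every random operation (splitting, folding, tuning, CNN
  initialization and shuffling, explanation sampling, generation) takes an
  explicit seed; identical configs give byte-identical artifacts.

## Known limitations

* Hashed-family analogues and generated keyed dictionaries are not
  bit-compatible with external descriptor software; use the import path
  for exact matrices.
* The permutation explainer's per-feature values (not their sum) carry
  sampling variance at small draw counts; symmetry between duplicate
  columns holds only in expectation.
* `SVC(probability=True)` calibrates with its own internal CV; its
  probabilities are slightly seed-sensitive by construction.
* The NumPy mCNN targets this architecture only (single conv layer, two
  classes) and is not a general deep-learning substrate.
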