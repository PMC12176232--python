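# Methods

## Problem setting

protclass models a binary screen over protein sequences: a positive class
of disease-associated proteins (the motivating use case is chronic myeloid
leukemia candidates from the BCL2/HSP90/PARP/RB families) against a
negative background, classified purely from sequence-composition
descriptors.  The package assumes single-chain amino-acid sequences over
the 20 canonical residues; nonstandard letters are handled by an explicit
policy (`drop_residue` by default, since public keyword dumps routinely
contain X/U/B; `reject` for strict runs; `map_to_exclusion` to drop whole
records).

## Encoders

**AAC** is the vector of per-residue percentage frequencies (sums to 100).
**DPC** counts ordered residue pairs over the L−1 overlapping windows.  Two
normalizations are supported: dividing by L−1 (`fraction`, the default;
vectors sum to 1 and are length-independent) and dividing by the number of
dipeptide types (`per400`; vectors sum to (L−1)/400 and scale with L).  The
`per400` variant appears verbatim in parts of the literature; it is
retained behind a flag for literal fidelity, but the default is the
community definition because a length-dependent descriptor confounds
composition with sequence length.

**PseAAC** follows Chou's classical formulation.  Three per-residue scales
— hydrophobicity, hydrophilicity and side-chain mass — are standardized to
zero mean and unit population variance over the 20 residues; the
dissimilarity between residues is the mean of the three squared
differences, and the tier-k correlation factor T_k averages that
dissimilarity over all residue pairs k positions apart.  The first 20
components are the residue fractions and the last λ are wT_k, all divided
by 1 + wΣT_k, so the vector sums to exactly 1 and reduces to the AAC
fractions at λ = 0.  Defaults are λ = 5 (giving the 25-dimensional
descriptor) and w = 0.05, the standard weight in this family of
descriptors.  The shipped property tables are the classical ones
(`src/protclass/data/physicochemical.tsv`) and can be replaced via
`--property-table`; a table is rejected unless it covers exactly the 20
canonical residues with non-zero variance.

Feature order is fixed (residues alphabetically; dipeptides row-major AA,
AC, …, YY) and written into every CSV header, so column order is
bit-stable across runs.

## Redundancy removal

Identity between two sequences is computed from an exact global alignment
with match +1, mismatch 0 and linear gap −1, as identical aligned columns
divided by the shorter sequence length — the denominator convention of
CD-HIT, whose behavior this module emulates at desk scale.  No k-mer
prefilter or banded heuristics are used: exact alignment is affordable for
thousands of sequences, which is the intended regime.  Greedy incremental
clustering visits sequences by descending length (ties broken by ascending
id, for determinism) and attaches each to the first representative at or
above the cutoff (default 0.6).  Deduplication clusters within each class
separately so that a positive sequence can never be absorbed by a negative
representative.  Among co-optimal alignments the implementation takes the
aligner's first; for substitution-only divergence the identity equals the
Hamming fraction, which the tests pin down.

## Preprocessing

*Outliers.*  Per feature, values outside the Tukey fence
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are flagged; a row is removed only when more
than 10 % of its features are flagged.  The row-fraction trigger prevents
high-dimensional DPC matrices (where some cell is always extreme) from
being annihilated.  Constant features flag nothing.

*Feature selection.*  Features are scored by the absolute point-biserial
(Pearson) correlation with the binary label; zero-variance features score
0.  Features below a threshold (default 0: keep all) are dropped, and the
survivors are scanned in descending score with any feature whose pairwise
|r| to an already-kept feature exceeds 0.95 pruned.  The kept names, all
scores and the rule that removed each feature are recorded in a report and
in model provenance.

*Augmentation.*  "Numerical replicas": each row yields factor−1 copies
jittered by Gaussian noise with sd = 0.01 × the feature's class-wise sd.
By default augmentation is applied to the training partition only — the
alternative, replicating before the split, places near-copies of training
rows in the test partition and turns held-out evaluation into memorization.
That pre-split mode is still available (`--augment-before-split`) because
it reproduces the protocol evidently used in parts of this literature,
where reported test-set sizes far exceed the number of distinct sequences;
results obtained with it measure replica recall, not generalization.

*Splitting.*  Stratified per class at a default test fraction of 0.25
(test size = floor per class, remainder to train), seeded.

## Classifier registry

Seven families with pinned settings: RBF-kernel SVC (C = 10⁴, γ = 10⁵,
degree recorded but inert under rbf, Platt probabilities enabled), random
forest (150 trees on DPC, 50 otherwise), 5-NN with Euclidean distance,
Gaussian naive Bayes with equal priors, XGBoost and decision tree (library
defaults, pinned explicitly), and L2 logistic regression (C = 10,
tol = 0.1).  Fitting is delegated to scikit-learn and XGBoost; the package
owns the contracts: deterministic training given a seed (single-threaded
tree learners), complete provenance in every archive, and a fixed decision
rule.

Two pinned configurations are degenerate, and the package documents rather
than repairs them:

- **SVC.**  With γ = 10⁵, the kernel value exp(−γ‖x−y‖²) underflows for
  any realistic pair of composition vectors (‖x−y‖² ≈ 0.01–0.03 on
  fraction scale); off-diagonal Gram entries survive only as subnormal
  floats.  The classifier memorizes its training set perfectly but can
  generalize only through a hard radius of ≈ √(745/γ) around training
  points.  When training classes are exactly balanced the intercept is
  exactly zero and the decision reduces to a radius-truncated
  nearest-neighbour rule; any imbalance produces a nonzero intercept that
  dominates the subnormal kernel terms, and every prediction collapses to
  one class.  Held-out accuracy is therefore bimodal (near-chance or
  1-NN-like) and crosses 90 % reliably only under pre-split augmentation.
  A related numerical consequence: the Platt calibration is fitted on
  cross-validated decision values that are numerically zero and can come
  out inverted, so SVC labels are taken from the margin sign (the SVM's
  own decision rule) while the Platt probability is reported as auxiliary
  output.  All other families threshold the class-1 probability at 0.5,
  ties to the positive class.
- **Logistic regression.**  tol = 0.1 halts the solver almost immediately;
  the model stays near its initialization and predicts (close to) the
  majority class.  This matches the qualitative behavior visible in the
  bundled reference tables, where the logistic rows show recall near zero
  and, on DPC, an all-negative confusion matrix (F1 = 0, specificity
  = 100).

## Evaluation

Metrics are percentages recomputable exactly from the TN/FP/FN/TP counts;
any metric with a zero denominator is 0 by convention (so TP = 0 forces
F1 = 0), which is required to reproduce the all-negative logistic rows of
the reference tables.  Display rounding is half-to-even at one decimal.
`table_check` compares recomputed metrics against printed cells: a range is
consistent when the value lies inside it with half-a-last-digit slack; a
point value is consistent when it equals the recomputation rounded *or*
truncated at its printed precision — the reference tables demonstrably mix
both display conventions, and several cells match only under truncation.
Of the 72 printed cells, 40 are consistent with their own confusion
matrices and 32 are not; the package reports both numbers and flags each
cell instead of choosing a side.

## Synthetic data

The generator draws negatives i.i.d. from the uniform residue composition
and positives from a composition in which the residues {A, L, K} (a fixed,
documented, configurable subset) have their probabilities multiplied by
1 + δ and renormalized; lengths are uniform on a range and everything is
seeded.  AAC and PseAAC are exactly the statistics this shift moves, so the
planted signal has an analytic ground truth and δ = 0 makes the classes
exchangeable.  The generator does **not** emulate real biology — no
domains, motifs, phylogenetic correlation, or family structure — so green
pipeline tests demonstrate correctness of the machinery, not clinical
performance on real CML data.  `plant_homologs` creates copies at a
controlled identity level (⌈(1−t)·L⌉ substitutions) and verifies the
achieved alignment identity rather than assuming it.

## Problem sizes and determinism

The test and acceptance workloads use 200 + 200 sequences of length
80–120 at δ = 2 (end-to-end), 1000 random sequences (encoder sum
properties) and ≤ 50 sequences (clustering against a brute-force oracle) —
sizes chosen so the full suite completes in seconds while keeping the
statistical checks well-powered.  Every stochastic operation is a pure
function of (input, config, seed); repeated runs produce bit-identical
feature matrices, models and report JSONs, which the suite asserts.

## Known limitations

- The acceptance suite deliberately keeps three red assertions: SVC
  end-to-end recovery above 90 % under the leakage-free default pipeline,
  and SVC/LR beating chance by a wide margin.  With the pinned
  hyperparameters these are unattainable without pre-split augmentation,
  for the reasons above.
- Global alignment is exact but quadratic; clustering millions of
  sequences is out of scope.
- Only the 20 canonical residues are modeled; selenocysteine and
  ambiguity codes are sanitized away rather than encoded.
- No probability calibration, ROC analysis, cross-validation aggregation
  or hyperparameter search: the registry reproduces fixed configurations.
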