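# Methods

## The model

`rotpssm` classifies protein pairs as interacting or not using only
sequence-derived information. Each protein is represented by its
Position-Specific Scoring Matrix (PSSM), the N × 20 integer log-odds
profile PSI-BLAST produces from iterative alignment against a large
reference database (the package wraps the external tool; it never
reimplements alignment). Downstream, only the 20 log-odds columns are
used; the weighted-percentage columns and trailing statistics of the ASCII
format are parsed past and discarded.

### Fixed-size standardisation

Two-dimensional PCA needs same-shape samples, but proteins differ in
length. The default standardisation maps the N × 20 profile M to its
length-normalised Gram matrix A = MᵀM / N: always 20 × 20, symmetric PSD,
and stable under protein length, since it is the average outer product of
the residue rows. The alternative `pad_truncate:20` (zero-pad or cut the
rows) is exposed for comparison but is length-biased; the Gram form is the
default for that reason. Raw log-odds are used as-is (`sigmoid: false`); a
logistic squash of the scores is available but off by default, since the
raw integer scores are the literal profile content.

### 2DPCA descriptor

Over training matrices V_1 … V_N the total scatter matrix is

    G_t = (1/N) Σ_i (V_i − V̄)ᵀ (V_i − V̄),

a 20 × 20 symmetric PSD matrix whose leading eigenvectors X_1 … X_d
maximise the projected scatter trace(Xᵀ G_t X). Projection is applied to
the centered sample, F_k = (V − V̄) X_k: centering matches the scatter
criterion (which is defined on centered data) and gives the clean
invariant that the mean matrix projects to the zero vector. The d
projections are flattened component-major into a length-20·d vector; a
pair feature is the concatenation [f_A ‖ f_B] in pair-list order (order
sensitivity is deliberate and documented — the pair list defines it).

Numerical conventions: eigenvectors come from a dense symmetric
eigendecomposition, are sorted by nonincreasing eigenvalue, and each axis
is sign-fixed so its first nonzero coordinate is positive, making the
basis reproducible across platforms. The default d is 20 (the full basis,
an exact isometry of the centered sample); users tune downward for speed.
The basis serialises to a single `.npz` archive and round-trips bit-exact.

### Rotation Forest

The ensemble is implemented from scratch. For tree i of L:

1. the n features are split uniformly at random into K disjoint subsets
   (sizes differ by at most one; remainder spread one per subset);
2. for each subset, a non-empty random subset of classes is drawn (each
   class kept with probability 1/2, resampled while empty), their samples
   bootstrap-sampled at fraction 0.75 with replacement;
3. all-component PCA on that sample, restricted to the subset's columns,
   yields an orthonormal loading block;
4. blocks are assembled into a sparse n × n rotation matrix in original
   feature order (entries outside the blocks are exactly zero), and an
   unpruned Gini CART tree is trained on the rotated data X·R_i.

Predicted confidences are the unweighted average of per-tree class
probabilities; the label is the argmax, ties to the lowest class index.
Per-tree probabilities are Laplace-smoothed (+1) leaf class frequencies
computed from stored leaf counts — smoothing keeps scores off exact 0/1,
which would otherwise collapse ROC resolution at small L. The per-tree
outputs are averaged without per-tree normalisation (the probabilities
already sum to one).

Defaults are K = 20 and L = 2, the grid-searched optimum reported for this
descriptor/classifier combination on yeast interaction data. The
bootstrap fraction (0.75) is the canonical Rotation Forest choice; the
class-subset rule and replacement flag are configurable, and the
deterministic "all classes, fraction 1.0, no replacement" setting reduces
a K = 1 rotation to plain full-data PCA — the configuration the test
suite verifies against an independent eigendecomposition oracle. PCA
centering is used when fitting each block, but the stored block is the
loading matrix only (no mean folded in), the standard formulation.

The base learner is scikit-learn's `DecisionTreeClassifier`; everything
around it — partitioning, class-subset bootstrap, rotation assembly,
confidence averaging — is this package's own code. All randomness flows
from one integer seed; identical seeds give bit-identical partitions,
rotations and predictions.

## Evaluation protocol

Metrics over the confusion table (positive class = interacting): accuracy,
sensitivity, precision, and MCC. Conventions: MCC is 0 when any factor of
its denominator is zero (the standard limit); precision is NaN when there
are no positive predictions, and NaN metrics are excluded from
aggregation with a warning. ROC curves sweep the decision threshold over
the unique positive-class confidences; AUC is trapezoidal, which equals
the tie-corrected two-sample rank statistic (a property test enforces the
equivalence against a pairwise-counting oracle).

Cross-validation is stratified: per label, a seeded shuffle followed by
round-robin assignment, so per-class fold sizes differ by at most one.
Within each fold the 2DPCA basis is fitted on the training-fold proteins
only — the leakage-free choice, made deliberately since fitting the
descriptor basis on all data inflates test metrics. Aggregates are mean ±
sample (n−1) standard deviation. Per-fold ROC is the default; a pooled
ROC is available by flag.

The cross-species mode fits basis and model on one dataset and evaluates
once on another, possibly with a disjoint protein universe. Curated
independent interaction sets are usually all-positive; there the
correct-classification rate coincides with sensitivity and is the only
reported metric, with precision/MCC/AUC flagged unavailable.

## Synthetic data

The generator emulates the *structure* of golden-standard PPI data, not
its content: balanced positive/negative pairs, with negatives drawn
across compartments. Proteins belong to latent clusters (default 2, the
two-compartment analogy); cluster centers are drawn N(0, δ²) per
coordinate in 20 dimensions, each protein's latent profile adds
within-cluster jitter (sd 0.5), and each residue row adds noise (sd 1.0)
before integer rounding and clipping to the PSI-BLAST log-odds range
[−10, 12]. Interacting pairs are sampled within a cluster, non-interacting
pairs across clusters, without duplicates. δ (the center spread) is the
single detectability dial: δ = 0 collapses the centers and removes all
class signal; the benchmark condition is δ = 3 with 500 balanced pairs.
Default protein lengths are uniform in [50, 200]. A `center_seed` lets two
datasets share generative parameters while containing disjoint proteins —
the cross-species setting.

What passing tests on this generator do and do not show: they validate the
descriptor/classifier chain end to end (parsing, standardisation,
projection, rotation, ensembling, the CV protocol, and its power and null
behaviour), but the latent-cluster model is far simpler than real
evolutionary profiles — no residue composition structure, no homology
between proteins, no hub proteins shared across many pairs, and a cleaner
class boundary than curated interactomes have. Metrics on this benchmark
are therefore statements about the pipeline's correctness and
sensitivity, not predictions of accuracy on real interaction data.

## Problem sizes and numerics

The validation suite runs the headline benchmark at 500 pairs with the
full default configuration (d = 20, K = 20, L = 2), and the repeated-seed
studies (null calibration, separation monotonicity, label permutation,
transfer) at 100–300 pairs with a reduced descriptor (d = 5, K = 5),
sizes chosen to keep repeated cross-validation runs cheap while leaving
the measured effects far from their thresholds. Tolerances: orthonormality
and eigen-equivalence at 1e-8; scatter symmetry, isometry, AUC/U-statistic
and confidence normalisation at 1e-10; metric arithmetic at 1e-12 against
exact rational/high-precision oracles.

Degenerate inputs: a class-subset draw with fewer than two samples is
retried a bounded number of times, then falls back to the full training
set (logged); single-class training sets, empty matrices, out-of-range K
or d, and malformed files are rejected with explicit errors.

## Known limitations

- The 40% sequence-identity / minimum-length redundancy filter applied to
  curated datasets is documented but not implemented (it requires an
  external clustering tool and the source data).
- Binary classification only; the confidence averaging extends to more
  classes but is untested beyond two.
- `run_psiblast` requires the external BLAST+ suite and a formatted
  database; all tests mock it.
- Alternative descriptors (auto-covariance, discrete cosine transform)
  are not implemented; the descriptor interface is pluggable so they
  could be added.
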