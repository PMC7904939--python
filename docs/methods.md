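# Methods

## Model

`simdta` predicts continuous drug–target binding affinities from similarity
structure alone.  Each drug i is represented by the vector **k**¹ᵢ of its
Tanimoto similarities to every drug in the training roster; each target j by
the vector **k**²ⱼ of its normalized Smith–Waterman similarities to every
training target.  A pair (i, j) is encoded as the outer product
**k**¹ᵢ ⊗ **k**²ⱼ — an n_d × n_t grid whose entry (a, b) is k¹ᵢₐ·k²ⱼᵦ.
Because self-similarity is 1, row i of the grid reproduces the target
similarity profile and column j the drug profile, so the grid carries both
the raw unimodal vectors and all their bimodal products.

The grid is regressed onto affinity with a small 2D CNN:

    conv(32, 5×5, valid) → maxpool(2×2, stride 1)
    → conv(18, 3×3, valid) → maxpool(2×2, stride 1)
    → flatten → dropout(0.1) → dense(128, ReLU) → dense(1, linear)

trained by Adam (learning rate 0.001, default moments), mean-squared-error
loss, batch size 32, 20 epochs, with per-epoch reshuffling under the run
seed.  Pooling is overlapping (stride 1 in both dimensions) and both
convolutions are unpadded, so each conv shrinks a spatial dimension by
k − 1 and each pool by 1; the minimum input extent is 9 in each dimension
and the flatten length is 18·(n_d − 8)·(n_t − 8).

The underlying assumption is the chemogenomic similarity principle: similar
compounds hit similar targets with similar strength, so the affinity of a
pair is predictable from where the pair sits in the joint similarity
structure of the training panel.  The model sees no atom-level or
residue-level features beyond what the two similarity measures capture.

## Similarities

**Drugs.**  RDKit's topological (linear-path) hashed fingerprint, 2048 bits,
path lengths 1–7 (the toolkit defaults), compared by the Tanimoto
coefficient |A∩B|/|A∪B|.  Two all-zero fingerprints are defined to have
similarity 1 (identical objects) with a warning; the bit length is
configurable.

**Targets.**  Optimal local alignment (Smith–Waterman) with affine gaps; a
gap of length L costs open + (L−1)·extend.  Raw scores are normalized as
SWᵢⱼ / √(SWᵢᵢ·SWⱼⱼ) so self-similarity is exactly 1.  Defaults: BLOSUM62,
gap open 10, gap extend 0.5 — the convention of the similarity-based
affinity-prediction literature; all three are configurable.  The
normalization is not provably bounded by 1 for arbitrary scoring schemes;
the matrix builder raises if an off-diagonal entry exceeds 1 beyond
floating-point tolerance.  Ambiguity codes are mapped (B→D, Z→E, U→C, O→K,
with a warning); X is kept and scored by the substitution matrix's own
low-penalty X column; any other letter is an error.  Alignment is computed
with Biopython's `PairwiseAligner`; the test suite checks it against an
independent exhaustive Gotoh dynamic program on short random pairs.

## Affinity scales

Kd panels are transformed to log space, pKd = −log₁₀(Kd/10⁹) with Kd in nM,
so 10,000 nM (the conventional weak-binder reporting floor) is pKd 5 and
higher means stronger binding.  KIBA-style scores, where lower means
stronger, are reoriented in three steps: negate, find the minimum of the
negatives, add its absolute value to all — an affine order-reversing map
whose minimum output is 0.  The shift depends on the score set, so any
threshold stated on the raw scale (e.g. a binarization cutoff) must be
supplied on the transformed scale as a configuration value rather than
recomputed.  The loader never transforms implicitly.

Missing cells are first-class: training uses observed pairs only.  A
similarity-weighted imputation utility (weights = target–target normalized
SW similarities, falling back to the plain mean when all weights vanish) is
provided for methods that require a dense matrix, but the CNN pipeline does
not use it.

## Cross-validation

k-fold CV partitions the observed pairs, constrained so that every target's
observations span at least `min_folds_per_target` distinct folds (default
k − 1: two folds for threefold CV, four for fivefold), ensuring no target
appears only in training or only in testing.  Construction deals each
target's pairs round-robin into a random fold ordering (which satisfies the
constraint whenever the target has enough observations) and then rebalances
fold sizes by moving only pairs whose target occupies the source fold more
than once, so the constraint is never violated.  Deterministic under the
seed.  No inner hyperparameter loop is run: all architecture and optimizer
constants are fixed.  Similarity matrices are computed once over the full
rosters, since the coverage constraint guarantees every entity occurs in
training folds; for genuinely unseen entities (case-study ranking) the
similarity vectors are computed against the training rosters only.

## Evaluation

* MSE — mean squared residual.
* Concordance index — fraction of strictly ordered label pairs predicted in
  the correct order, ties in predictions counting ½; label ties are
  excluded from both numerator and normalizer.  Computed by a vectorized
  O(n²) pairwise comparison, checked against a literal double loop.
* r_m² = r²·(1 − √|r² − r₀²|), where r² is the squared correlation of the
  with-intercept least-squares fit of predictions (ordinate) on observed
  values (abscissa) and r₀² the through-origin analogue.  The absolute
  value guards the root when r₀² > r², which real data can produce; both
  orientation and the absolute value follow the established r_m²
  validation literature.
* AUPR — labels binarized at a threshold (pKd 7.0; transformed-KIBA 12.1 by
  convention), predictions ranked on the matching orientation, and the
  precision–recall curve integrated step-wise (average precision, no
  trapezoidal interpolation); tied scores share one PR point.

Per-fold values are reported with their mean and standard error
(sd/√k).  Folds whose binarized test labels are single-class report AUPR as
NaN with a warning, and likewise r_m² under zero variance; summaries are
NaN-aware.

## Numerical choices

The CNN is implemented directly on NumPy arrays (im2col convolution,
shifted-view overlapping pooling with first-argmax gradient routing,
inverted dropout); analytic gradients are verified against finite
differences in the test suite, and training is bit-reproducible under the
seed.  Weights use Glorot-uniform initialization with zero biases, except
the output bias, which is initialized at the training-target mean.  That
choice (equivalent to centering the targets) matters at small sample sizes:
with a few hundred training pairs the fixed 20-epoch budget provides only
~10² optimizer steps, and starting the regression head at 0 spends most of
them learning the affinity offset (~5 pKd units) rather than structure.  It
is applied unconditionally at every scale and is a no-op asymptotically.

Epochs = 0 returns the initialized network; predictions run with dropout
disabled, are pure functions of (weights, input), and are invariant to
batch partitioning.  Models persist as a directory holding a plain-text
JSON manifest (format version, hyperparameters, rosters, optionally the
roster SMILES/sequences needed to embed unseen candidates) plus an `.npz`
weights blob; loading reconstructs the layer stack and restores weights
exactly.

## Synthetic data

The generator emulates the *shape* of a kinase-panel study at desk scale.
Drugs are built as cluster scaffold + homologous alkyl chain + cycled
terminal substituent, which guarantees chemical validity by construction
and makes within-cluster Tanimoto exceed between-cluster on average.
Targets are per-cluster random consensus sequences (length 100–300) with
10% per-position mutations per member.  Affinities are
y = 5.0 + s·E[c_d, c_t] + N(0, σ), with the cluster-effect matrix E drawn
once per seed from a standard normal, s the signal strength and σ the noise
level; cells go missing independently.  Defaults: 20 drugs × 15 targets,
4 × 3 clusters, s = 2.0, σ = 0.3, 10% missing.

Because affinity depends on pair identity only through cluster membership,
which is recoverable from the similarity structure, a similarity-based
model can recover the signal; the end-to-end test trains on four fifths of
the observed pairs and checks held-out concordance above 0.70 and MSE below
the constant-mean baseline.  The generator does **not** reproduce real
kinase chemistry, realistic affinity distributions (e.g. the strong weak-
binder peak at pKd 5 in Kd panels), correlated missingness, or assay noise
heterogeneity — so passing tests demonstrate that the pipeline recovers
similarity-driven structure, not that it attains any particular accuracy on
real panels.

## Problem sizes

The test suite and the reproduction script run entirely at desk scale: the
20 × 15 synthetic panel (~270 observed pairs) for end-to-end training,
sequences ≤ 50 residues for alignment-oracle comparisons, and ≤ 200-element
vectors for metric-oracle comparisons.  Benchmark-scale panels (tens of
thousands of pairs) are supported by the same code paths — grids can be
built lazily per batch — but are not exercised by the tests.

## Known limitations

* Similarity vectors are defined against the training roster, so prediction
  quality for entities far from every training cluster degrades gracefully
  but silently (their similarity vectors approach zero, and the outer
  product grid carries little signal).
* The concordance-index implementation is O(n²) in memory and time;
  adequate through tens of thousands of pairs, not for millions.
* The fold-size rebalancing pass is heuristic: it guarantees the coverage
  constraint and near-balance in practice but not a worst-case balance
  bound.
* Raw-KIBA orientation (`positive_is_high=False`) is supported in the
  metrics, but model training assumes higher-is-stronger scales; transform
  first.
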