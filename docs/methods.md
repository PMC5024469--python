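# Methods

This note documents the models, numerical choices and known limitations of
the `hmclmlp` package in enough detail to reproduce or audit any number it
outputs.

## Class hierarchies and the consistency constraint

A taxonomy is a rooted tree of classes identified by their token path from
the root (`12.01.01`).  A synthetic root joins the top-level categories; it
is never a class, never predicted, and not counted in |C| (FunCat's 28 top
categories have no explicit common parent).  The class ordering is
lexicographic by path tokens, frozen at build time, and used by every
vector and matrix over C — per-level column indices map into this single
global ordering.  Path tokens are compared as strings (`"01"` ≠ `"1"`);
both the dot dialect used in print and the slash dialect used by the Clus
ARFF files are parsed, and no numeric normalization is applied when mixing
them.

Label sets are ancestor-closed on load.  Prediction repair removes any
predicted class whose parent is not predicted, sweeping level-ascending so
removals cascade to all predicted descendants; the result is the unique
largest ancestor-closed subset of the input, and the operation is
idempotent.  A useful identity used throughout: thresholding at t followed
by cascading repair keeps class j exactly when the minimum score along j's
root path is ≥ t, so threshold sweeps operate on min-path-transformed
scores instead of repairing at every threshold.

## Data ingestion and preprocessing

The Clus hierarchical ARFF dialect (`@ATTRIBUTE class hierarchical
path,path,...`, labels as slash paths joined by `@`, `?` for missing) is
parsed by a dedicated reader because the `hierarchical` attribute type is
not valid standard ARFF.  The hierarchy is the union of the declared
vocabulary and the observed labels.  Errors carry line numbers.

Preprocessing, in order:

1. **Imputation** — missing numeric values are replaced by the training
   split's column mean, missing nominal values by the training split's
   mode over category values (declaration order breaks ties).  Statistics
   always come from the training split, also when transforming the
   validation and test splits, to avoid leakage; imputation precedes
   encoding because a mode is defined on categories, not on encoded
   columns.
2. **Encoding** — one-attribute-per-value: a nominal attribute with k
   categories becomes k columns valued +1 (presence) / −1 (absence), in
   declaration order; numeric attributes pass through.
3. **Standardization** — every column (encoded ±1 columns included) is
   standardized to mean 0, variance 1 with *population* (divide-by-m)
   variance computed on the training split; a `sample_variance` flag
   switches to the n−1 form.  Zero-variance columns map to all-zeros.
   Validation instances are not pooled into the statistics.

## The per-level learner

Each level's network is a single-hidden-layer perceptron, logistic
φ(z) = 1/(1+e^(−z)) in both layers, biases stored as the last row of each
weight matrix.  Training is stochastic (per-instance) backpropagation of
the half squared error E = ½Σⱼ(oⱼ−yⱼ)², with momentum:

    Δw(t) = −lr · ∂E/∂w + momentum · Δw(t−1)

with separate learning rate and momentum for the hidden and output layers
(defaults 0.05/0.03 and 0.03/0.01).  Instances are visited in a freshly
seeded shuffled order each epoch; weights initialize uniformly in
[−0.1, 0.1].  No weight decay, adaptive rates, or mini-batching.  Hidden
width is round-half-up(fraction × inputs) with a floor of one neuron;
per-level fractions default to 0.6/0.5/0.4/0.3/0.2/0.1 (deeper levels have
fewer annotated instances, so capacity shrinks with depth; hierarchies
deeper than six levels reuse the last fraction).  The epoch seed stream for
level l is derived from (seed, l) only, so all variants share bitwise
identical level-1 networks under the same seed — the variants genuinely
differ only from level 2 on.

Gradient correctness is verified against central finite differences
(h = 1e−5).  The comparison divides by max(|finite difference|, 1e−4):
below that scale the difference quotient's own float64 roundoff
(≈ 5e−12 absolute) dominates, and a pure relative comparison would report
spurious errors regardless of implementation.  Real gradient defects scale
with the gradient and are caught on the large components.

## Orchestration and early stopping

Levels train strictly root-to-deepest; finished networks are frozen.  The
level-l training set is the subset of instances with at least one level-l
annotation (with closed labels these subsets are nested).  Augmentation
inputs during training are the frozen previous network's raw scores over
all training instances (Predicted, Labels) or the true previous-level
labels (True); at prediction time every variant uses the previous
network's raw scores, and every test instance traverses every level.  The
augmentation block precedes the feature block; the order is fixed and
carries no meaning.  A level with no annotated training instances is
skipped and contributes zero scores (and a zero augmentation block) from
then on.

After each epoch of level l the validation AU(PRC) pooled over all classes
of levels 1..l is computed — over all validation instances, using the
frozen earlier networks plus the current weights, with repair applied —
and the best-scoring weights are snapshotted.  Training of the level stops
when this value has not strictly exceeded the best for 10 consecutive
epochs (patience, configurable) or at `max_epochs` (default 200); the best
snapshot is retained.  Decoding thresholds scores at a configurable value
(0.5 default for label output) and repairs; evaluation itself is
threshold-free.

## Evaluation

PR points pool TP/FP/FN over a class scope at each threshold, with
predictions repaired before counting, so the metric scores exactly the
label sets a user would receive.  Precision at TP+FP = 0 is defined as 1.
The curve is swept at every distinct (min-path-transformed) score value;
no fixed grid.  The area interpolates between consecutive achievable count
pairs (TP_a, FP_a) → (TP_b, FP_b) linearly in count space, one unit of TP
at a time — the intermediate precision at TP_a+i is
(TP_a+i)/((TP_a+i) + FP_a + i·(FP_b−FP_a)/(TP_b−TP_a)) — and sums one
rectangle of recall width 1/Pos per unit of TP.  Interpolating from the
(0, 0) count anchor makes the recall-0 end a constant extension of the
first achievable point's precision; with all scores identical the single
achievable point yields area = prevalence.

A `method="step"` mode computes the area with no interpolation (each
recall increment credited with the precision of the point achieving it),
matching a brute-force fine-grid threshold sweep to grid precision.  The
two modes coincide when all pooled scores are distinct, because then
consecutive achievable points differ by a single sample.  They differ
visibly on hierarchical scores: the min-path transform assigns every class
its lowest-scoring ancestor's value, creating tied blocks that the
interpolated rule credits with intermediate precisions and the step rule
credits with the block's final precision.  On small random hierarchical
fixtures the gap is typically around 1e−3 and can reach ~7e−3 — an
inherent difference between the two area conventions, not an integration
tolerance.

Per-class areas are computed from the same transformed scores; classes
with no positives in the evaluated split have no defined area, are
excluded from the per-class averages, and are listed in the report, with
frequency weights renormalized over the evaluated classes.  Frequency
weights default to the evaluated split's closed label matrix.  Per-level
AU(PRC) pools each level's classes.

Method comparison ranks methods per dataset in descending metric order
(average ranks on ties) and averages ranks across datasets.  The Nemenyi
critical difference is CD = q_α·√(k(k+1)/(6N)), with q_α computed from the
studentized range distribution at infinite degrees of freedom divided by
√2 (α ∈ {0.05, 0.10}); two methods differ significantly when their mean
ranks differ by at least CD.  Win/loss class sets count, per class, the
datasets where one method's per-class area strictly exceeds the other's;
ties count for neither.  The package ships the published 10-dataset ×
8-method score matrices for the FunCat yeast benchmarks
(`hmclmlp.published`) as reference inputs for this machinery; feeding them
through `average_ranks` reproduces the published average ranks exactly.

## Synthetic data

The generator emulates the structure of the FunCat benchmarks without
reproducing any real microarray covariance.  A complete branching-ary tree
of depth ≤ 6 carries one prototype vector per class: level-1 prototypes
are spherical standard normal; each child is its parent plus (1−ρ) times a
fresh spherical normal offset.  ρ ∈ [0, 1] is the single knob coupling
levels: at ρ near 1 siblings are nearly indistinguishable from the
features alone while the parent's identity remains informative — precisely
the regime where augmenting a level's input with the previous level's
predictions should help.  Each instance draws 1 + Poisson(λ) leaf classes
by independent uniform root-to-leaf walks (λ = 0.5 default, so multi-path
annotation is common but not dominant), its labels are the ancestor
closure of those leaves (closure and parent≥child frequency monotonicity
hold by construction), and its features are the mean of its leaf
prototypes plus N(0, σ²) noise per coordinate (σ = 0.5 default — at
ρ = 0.9 sibling prototypes differ by offsets scaled to 0.1, so the noise
dwarfs the sibling separation and discriminating siblings from features
alone is genuinely hard).  Optional nominal attributes are tercile-binned copies
of the first feature columns; missing markers are inserted independently
at `missing_rate`.  Splits are unstratified seeded thirds, mirroring the
train/validation/test organisation of the public datasets.

Defaults (depth 3, branching 2, n = 900, p = 20, ρ = 0.9) are the
package's standard dependence benchmark: 14 classes, ~300 instances per
split.  The benchmark caps per-level training at 60 epochs — early
stopping fires first in almost every run — so a full 10-seed, two-variant
replication takes about a minute on one CPU.  What passing this benchmark
shows is that the Predicted variant exploits parent→child label
dependence that the features alone do not expose; it does not show
anything about real gene-expression data, whose feature correlations,
class imbalance (hundreds of mostly rare classes) and annotation noise the
generator deliberately does not model.

## Known limitations

* Tree hierarchies only; DAG taxonomies (e.g. the Gene Ontology) are out
  of scope, as are sparse/relational ARFF files.
* The two PR-area conventions (interpolated vs step) differ on tied
  hierarchical scores, as described above; comparisons between packages
  should fix one convention.
* Training is CPU-bound per-instance backpropagation; wall time grows
  linearly in instances × weights × epochs, and no GPU path is provided.
* The stochastic benchmark's margin (Predicted − NoLabels) is a few
  thousandths of AU(PRC) under the default conditions; single-seed
  comparisons are noise-dominated and only the multi-seed mean is
  meaningful.
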