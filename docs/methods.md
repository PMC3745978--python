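# Methods

`abcfs` implements a two-phase diagnostic-classification pipeline for
tabular biomedical data: wrapper feature selection driven by a
swarm-trained prototype classifier, followed by a linear support vector
machine evaluated with stratified k-fold cross-validation.

## The ABC optimizer

The artificial bee colony (ABC) is a population metaheuristic over a
box-bounded continuous space. A colony of size 2·SN maintains SN food
sources (candidate solutions) `z_i` with cost `f_i ≥ 0` and nectar fitness

    fit_i = 1 / (1 + f_i).

Each cycle runs three phases:

1. **Employed phase.** Every source proposes a one-coordinate move against
   a random partner k ≠ i,

       v_ij = z_ij + φ · (z_ij − z_kj),   φ ~ U[−1, 1], j ~ U{1..D},

   and keeps the candidate under greedy selection (equal-or-lower cost
   accepts; the trial counter resets on acceptance, increments otherwise).
2. **Onlooker phase.** SN roulette draws with probabilities
   `p_i = fit_i / Σ fit_n` each trigger the same move/greedy step on the
   drawn source.
3. **Scout phase.** At most one source per cycle — the one with the
   largest trial count, if it exceeds `limit` — is re-seeded uniformly:
   `z_ij = z_min,j + u · (z_max,j − z_min,j)`.

Control parameters and defaults: colony size 20 (SN = 10), `max_cycles`
300, `limit` 200. The best-ever position/cost is tracked across all
evaluations, so the reported trajectory is nonincreasing by construction.

Numerical/design choices where the formulation is open:

- **Out-of-box candidates** are clamped to the boundary, keeping the cost
  function's domain total.
- **Equal cost accepts the candidate** (greedy "equal or more nectar").
- **One scout per cycle** (the standard formulation); with `limit = 0`
  this still turns over the population steadily without collapsing it.
- **Vectorized phases.** All random indices and step sizes of a phase are
  drawn in bulk and all candidates evaluated in one batched cost call.
  Onlooker candidates are built from the positions at the start of the
  phase and acceptances applied in draw order; this differs from the
  strictly sequential formulation only when a source is drawn twice in
  one phase. The same engine evolves R independent colonies in parallel,
  which is what makes repeated subset scoring affordable.
- **Randomness.** One `numpy` Generator per run with a documented draw
  order per cycle; runs are bit-reproducible from the config seed.

## Supervised clustering as a subset scorer

For a labeled training set restricted to a candidate feature subset, each
class c is summarized by prototype centers found by minimizing the
normalized within-class cost

    f(z) = (1 / D_train) Σ_j d(x_j, z),

the mean *plain* Euclidean distance to the class's training samples (its
exact minimizer is the class's geometric median; the classical
squared-distance clustering objective and the cluster mean are provided
separately as diagnostics). The search box per class is the min/max of
that class's training samples per dimension — the smallest box guaranteed
to contain both mean and median. All SN final food sources are kept as the
class's prototypes (stored best-first), and a test point takes the label
of the single nearest prototype across classes, ties going to the earlier
class in `class_set` order. A best-prototype-only mode is deliberately not
the default: the full food set represents the class.

A feature subset's score is the held-out accuracy of this classifier:
draw a stratified 75/25 train/test split (per class,
`floor(0.75 · n_class)` rows to train), train per-class prototypes on the
train part, classify the test part, repeat `runs` times (default 100;
tests and the acceptance script use 10–20 for problem-size reasons), and
average. Each (step, candidate) evaluation derives an independent seed via
`SeedSequence` mixing; the `runs` repetitions are evolved as one batched
colony ensemble. A `fixed_split` mode reuses a single split across runs
for sensitivity analysis.

## Greedy forward selection and the stopping rule

Selection starts from the empty set; each step scores every unselected
feature appended to the current subset and accepts the argmax of the mean
score (ties to the lowest feature index). Selection stops when the
step-best mean score falls strictly below the previous step's score
(`min_improvement` shifts this threshold; default 0), when `max_features`
is reached, or when no features remain. The declining step's feature is
not kept; the full trace — per-step candidate scores, standard deviations,
and the rejected step — is recorded.

**Known limitation (measured, not hypothetical).** On class-conditional
Gaussian data a nearest-prototype rule projects onto the class-mean
difference, so appending an isotropic noise feature leaves its true
accuracy nearly unchanged; on a fixed finite dataset under repeated
resplits, pool-level sampling fluctuations of a noise column are even
shared between train and test, making noise features look very slightly
beneficial. Meanwhile the per-step argmax over several noisy candidate
scores carries a winner's-curse bias of roughly one standard error. The
net effect is that the strict-decline stop tends to fire late on such
data: informative features are reliably ranked first (recall of the
informative set is high), but the stopping point is a weak instrument for
the informative/noise boundary at moderate evaluation counts. Users who
need a hard subset size should set `max_features`; users relying on the
decline rule should increase `runs` and consider `min_improvement > 0`.

## SVM stage

The reduced data goes to a linear SVM trained by SMO (scikit-learn's
`SVC`, i.e. libsvm) under the dual constraints `Σ y_i α_i = 0`,
`0 ≤ α_i ≤ C`. Configuration mirrors the standard SMO setup: linear
kernel, KKT tolerance 1e-3, iteration cap 15000, kernel cache 5000 MB,
and C = 1.0 (exposed as a flag). The two classes map to −1/+1 by
`class_set` order; prediction is computed from the extracted hyperplane as
`sign(w·x + b)`, with the boundary itself assigned to the positive class.
libsvm's SMO is deterministic from zero initial multipliers, so no
randomness enters this stage. Non-convergence within the iteration cap is
recorded in the model's diagnostics rather than raised.

## Evaluation

Binary performance is reported from confusion counts with a designated
positive class (for the packaged medical schemas: the disease/positive
test label): accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
PPV TP/(TP+FP), NPV TN/(TN+FN). Any metric with a zero denominator is
reported as undefined and flagged — never silently zero. Cross-validation
is stratified k-fold by default (k = 10 in the pipeline); the mean of
per-fold metrics is the headline number, with pooled-confusion metrics
reported alongside for transparency. Plain shuffled k-fold
(`stratify=False`) supports any k up to leave-one-out. Feature selection
runs once on the full data before cross-validation (select-then-CV); this
mirrors the two-phase design but means the CV estimate does not account
for selection variability.

## Data handling

The readers accept headered CSV and the header-less UCI `.data` dialect
with `?` as missing marker; packaged schemas describe the hepatitis, BUPA
liver-disorders, and Pima diabetes layouts (column kinds, documented valid
ranges — violations warn but keep the value — and 1/2 binary codings
mapped to 0/1). Missing cells are imputed by the most frequent observed
value of the feature within the sample's own class, ties to the smaller
value; a per-class mean policy is available for continuous data. Optional
min-max scaling maps each feature to [0, 1] with parameters reusable on
held-out rows (out-of-range values clip and flag; constant features map
to 0). Scaling defaults on for real mixed-scale tables and off for
synthetic fixtures, which are generated on a common scale.

## Synthetic benchmark

The generator draws class-conditional Gaussians: informative coordinates
have unit within-class sigma and class means `class_separation` apart in
Euclidean distance across the informative subspace (spread evenly per
coordinate, so difficulty does not depend on how many coordinates carry
the signal); noise coordinates come from one shared zero-mean Gaussian
with `noise_sigma` (default 1), carrying no label information. Columns are
randomly permuted and the informative index set returned as ground truth;
missing cells can be inserted at a configurable rate. Defaults — 100
samples per class, 3 informative + 7 noise features, separation 4 —
define the benchmark condition used throughout the tests: strong enough
for a prototype classifier to work well on the informative subspace, weak
enough that subset scores are noisy and the stopping rule is genuinely
exercised. What this fixture does *not* emulate: correlated features,
heavy-tailed or multimodal classes, discrete/binary clinical codes, and
label noise — passing tests therefore demonstrate correctness of the
machinery in its intended unimodal regime, not performance on real
clinical tables.

## Problem sizes

The test suite and `scripts/acceptance.py` run the optimizer at its
defaults (SN = 10, 300 cycles) but keep evaluation counts modest as the
package's own benchmark sizes: 20 runs per subset evaluation and 20 seeded
selection experiments in the recovery tests (8 in the acceptance script),
100 runs for the null-calibration score, 10 runs per evaluation in the
end-to-end pipeline example.
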