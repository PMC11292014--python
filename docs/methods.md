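# Methods

## Relative-expression tests

A pair test on proteins (a, b) asserts `x_a < x_b` within a sample (strict
comparison; an exact tie counts as "not less", which keeps the test
deterministic under the usual TSP convention).  Its score on a binary task
is `delta = |f0 - f1|`, where `f_c` is the fraction of class-c samples —
among those with both values measured — satisfying the assertion.  Ties in
delta are broken by `gamma`, the between-class difference of the mean
within-sample rank gap `rank(b) - rank(a)` (ranks over all proteins in the
sample), then lexicographically by protein id, giving a reproducible total
order.  Samples missing either value abstain: they are excluded from both
`f_c` and `gamma` rather than imputed, preserving the rank-only semantics.
Pair directions are collapsed by orienting each pair so that `f0 >= f1`.

Consequence (tested property): every pair test, multi-test and tree decision
is invariant to any strictly increasing transform applied to a sample's
values — positive affine, log, rank.

## ReliefF discrimination weights

Candidate proteins are ranked by ReliefF.  Missing values are imputed per
protein by the class median *for distance computation only*; neighbours are
found by Manhattan distance on within-sample ranks (scale-free, matching the
order-test semantics); the weight updates themselves are the standard
hit/miss contrasts on the imputed values, normalized by each protein's
observed range.  This split matters: if the updates also used within-sample
ranks, a protein constant across samples could still receive weight (its
rank varies with the other proteins), whereas with value contrasts it scores
exactly 0.  Weights are clipped at zero and scaled by their maximum to
[0, 1].  The weight vector drives three things: the candidate pool for pair
search (top-K proteins, default K = 200, bounding the O(P²) pair scan), the
rank term of the fitness, and the proposal distribution of the
protein-swap mutation.

## Multi-test nodes

An internal node holds a primary pair and up to `max_surrogates` surrogate
pairs whose induced split agrees with the primary on a fraction ≥ θ of
co-evaluable training samples (default θ = 0.8; agreement is computed over
samples where both tests are non-abstaining).  Surrogates share at most one
protein with the primary — a surrogate repeating both proteins adds no
information — and are kept sorted by similarity.  Prediction is an
equal-weight majority vote of all member tests; an exact tie is resolved by
the surrogate votes alone (so surrogates can override the primary), and a
remaining tie or a fully-abstaining node falls back to the branch that held
the training majority class.  A node with an odd number of voting tests can
never reach the fallback.

## Evolutionary induction

Individuals are trees of depth ≤ 4 (configurable).  Initialization grows
each tree greedily on a stratified bootstrap of the training samples: at
each node the split is drawn uniformly from the 10 best pairs, recursion
stops at the depth cap, at node purity ≥ 0.95, or below 5 samples.  The
engine draws each node's surrogate count uniformly from 0..max_surrogates so
the initial population spans bare pairs to saturated clusters — without
this, the rank term (mean ReliefF weight over *all* proteins used) makes
surrogate partners dilute otherwise-optimal nodes and the search plateaus
short of simpler optima.

Selection is linear-ranking with pressure s (default 1.8):
`p(rank r of n) = (2 - s)/n + 2 r (s - 1)/(n (n - 1))`, best rank r = n - 1,
sampled with replacement; the top `elitism_count` individuals (default 1)
are copied verbatim, which makes generation-best fitness monotonically
non-decreasing (a tested invariant).  Crossover exchanges uniformly chosen
subtrees (a leaf counts as a subtree); identical parents reuse the same
crossover point so self-crossover is a no-op; depth-cap violations are
repaired by truncating over-deep subtrees to their majority leaves.
Mutation is two-level, each level firing independently with
`mutation_prob` (default 0.2): level 1 edits structure (replace a node's
multi-test with a fresh top-pair split, collapse a node to a leaf, expand a
leaf), level 2 edits one cluster (swap a primary protein for a pool protein
drawn with probability proportional to its ReliefF weight, add/remove/
replace a surrogate, flip a test's direction).  Leaf counts are refitted on
the full training set after every structural change.

Fitness is the scalarized sum
`F = w_acc·accuracy + w_cons·consistency + w_rank·rank_score − w_comp·n_internal`
with defaults (1.0, 0.1, 0.1, 0.02).  Consistency is the mean over internal
nodes of the mean surrogate similarity, counting surrogate-free nodes as
1.0 so simple nodes are not penalized; rank_score is the mean ReliefF weight
of all distinct proteins used (0 for a bare leaf).  Accuracy is training-set
accuracy.  The loop stops after `max_generations` (200) or
`stall_generations` (30) without best-fitness improvement, and the best tree
is pruned bottom-up: an internal node is replaced by its majority leaf
whenever that does not decrease fitness on the training data; the pass is
idempotent.  Defaults (population 64, crossover 0.8, pressure 1.8) are
conventional EA settings, recorded in the config for reproducibility.

All randomness flows from a single integer seed through one
`numpy.random.Generator` in a fixed call order; two runs with the same
config and seed produce byte-identical serialized models.

## Differential-expression cascade

Stage order: (1) presence — a protein is eligible iff measured in
≥ `presence_fraction` (default 0.5) of the task's samples; (2) peptide
confidence — ≥ `min_unique_peptides` (default 2) unique peptides;
(3) per-protein two-sided Welch t-test on log2 intensities of eligible
proteins (unpaired Wilcoxon rank-sum by flag; the groups are independent
subjects, so a paired signed-rank test does not apply); (4) Benjamini–
Hochberg over exactly the tested set (the multiplicity universe is
pre-specified as the gate survivors); (5) effect gate |log2FC| ≥ 0.585
(log2 of 1.5 — a 50 % expression difference); (6) FDR gate q < 0.05.
`significant` is the conjunction of all flags; the emitted table covers
every protein, including failures, with `-log10 p` as a reporting column
only (it is not an extra filter).  log2FC is the difference of group means —
the matrix is log2 by convention, so this is the log ratio of geometric
means; groups with fewer than two measured values yield a missing log2FC.

Known behaviour on the synthetic default cohort (two correlated biopsies per
participant): treating biopsies as independent replicates makes the Welch
test mildly anticonservative, and the unique-peptide gate removes the ~5 %
of proteins that draw a single peptide under the 1 + Poisson(3) count model.
Measured over 20 default cohorts, sensitivity for planted |log2FC| ≥ 1
proteins is ≈ 0.86 with observed FDR ≈ 0.08–0.12; a participant-averaged
variant (valid for the repeated-measures design) lowers the FDR to ≈ 0.03 at
the cost of power.  Both numbers are recomputed by `scripts/acceptance.py`.

## Cross-validation harness

Stratified k-fold (default k = 10) with per-fold class counts balanced to
within one sample; when participant ids are supplied, both biopsies of a
participant stay in one fold (grouped stratification — naive CV would leak
person-level signal).  Runs × folds are fully seeded
(`seed = base + run·10⁴ + fold`).  Metrics per fold: accuracy; AUC as the
rank (Mann–Whitney) statistic on the positive-class probability with half
credit for ties (undefined and reported as missing for single-class truth
vectors); F1 as the macro average of per-class F1; WF1 support-weighted;
confusion matrices with rows = truth.  Leaf probabilities are Laplace-
smoothed, `(count + 1)/(n + 2)`, so AUC is well defined for discrete leaf
scores.  Protein-selection frequency is accumulated from every fitted
tree's distinct-protein set, and multi-task overlaps are reported as
Venn-style exclusive regions.  Algorithm comparison uses the Friedman rank
test (midranks, tie-corrected statistic) followed, when significant, by all
pairwise Dunn z-tests with Bonferroni family-wise adjustment.  Baselines
(entropy tree, CART, random forest, SVM, naive Bayes) run on per-dataset
z-scored, median-imputed values via a thin adapter; the order-relation trees
need neither transform.

## Synthetic cohort generator

The generator emulates the study design end to end:

```
x[p, s] = mu_p + b[subj(s)] + delta_p · 1[class(s) ≠ reference] + offset_p(class) + eps
```

with `mu_p ~ N(20, 2²)` (log2 scale), participant effect `b ~ N(0, 0.5²)`
shared by both biopsies of a subject, residual `eps ~ N(0, 0.7²)`.  Groups
default to 13/11/8 participants (NG/PD/T2D) × 2 biopsies = 64 samples,
1139 proteins.  100 DE proteins draw `|delta|` uniformly from
[0.585, 2.0] with random sign (the order of magnitude of the study-scale
significant sets); reversal-pair proteins share a base mean and get class-
dependent offsets ±gap/2 with opposite signs so the pair's within-sample
order flips between reference and non-reference classes — note this also
makes them genuinely differential with |log2FC| = gap.  Missingness is
logistic in intensity, `P(missing) = σ((16 − x)/1.5)` by default (~10 %
of cells, concentrated in low-abundance proteins, the MNAR signature of
DIA); unique peptide counts are `1 + Poisson(3)`.  The external replica
draws new participants (default 11 + 10 × 2 = 42 samples) under the same
law restricted to a random shared-protein subset (default 645) plus a
per-protein batch offset `N(0, batch_sd²)`.

What the generator does *not* model: protein–protein correlation beyond the
planted pairs, non-normal intensity distributions, peptide-level effects,
batch trends within a dataset.  Passing tests therefore demonstrate
correctness of the algorithms under the declared generative law, not
performance claims about any real cohort.

## Numerical and degenerate-input choices

Per-dataset standardization (baselines only) uses the population (n)
standard deviation; zero-variance rows standardize to 0 with a warning
rather than erroring, so merged runs survive constant proteins.  Missing
sentinels in TSV input are {empty, NA, NaN, nan}; anything else non-numeric
fails fast.  Probability argmax ties break toward the class listed first in
the task definition.  Fitness comparisons use a 1e-12 improvement margin.
The problem sizes used by the test suite and the acceptance script (e.g.
500-protein recovery cohorts, 20-replicate DE studies, 50-instance oracle
sweeps) were chosen so the full suite completes in a few minutes on one CPU
while keeping every check statistically meaningful; they are stated in the
respective tests.

## Known limitations

Binary tasks only (the three-class design is analysed as the three pairwise
tasks); no k-TSP ensembles or weighted voting; the evolutionary defaults are
declared conventions, not values tuned to any dataset; the DE cascade tests
samples, not participants, by default (see above for the measured
consequences); DOT output is plain text — rendering requires an external
Graphviz installation.
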