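# Methods

## The recorder model

A colony starts from one founder cell carrying L recording units, all in the
ground state. Cells divide synchronously; after d divisions the colony has
N = 2^d cells. At every division, each still-unedited unit of each daughter
edits independently with probability μ and, if it edits, lands in state
s ∈ S with probability α_s (Σ α_s = 1). Editing is irreversible: along any
root-to-leaf path a unit changes state at most once. The simulator
(`simulate.simulate_colony`) implements exactly this process and retains the
internal-node barcodes for testing; reconstruction only ever sees the leaf
barcodes.

Two stock alphabets mirror the common experimental systems: a three-state
integrase recorder (ground '1', deletion '0', inversion '2'; L = 10) and a
two-state substitution recorder (ground '0', mutated '1'; L in the
thousands). `Alphabet.with_n_edits(k)` generalizes to k edit states.

Defaults for the shallow-colony study conditions: editing rate μ = 0.15
(the posterior mean estimated for the three-state system), uniform α_s =
1/|S| as used for simulation, and colony depths drawn uniformly from
{2,...,6} so colony sizes span 4–64 cells, bracketing the 4–39-cell range of
real colonies. The empirical depth distribution of the real dataset is not
tabulated anywhere we can consume, so the uniform bracket is used; it is
configurable in `SimConfig`.

## Editing-model inference

Because internal states are unobservable, the division at which an edit
occurred is marginalized: after d divisions a unit is unedited with
probability (1−μ)^d and in state s with probability
Σ_{k=1..d} (1−μ)^{k−1} μ α_s = α_s (1−(1−μ)^d). Units and cells are
conditionally independent given division counts, so the likelihood depends
on the data only through the counts of (depth, state) pairs —
`ObservationSet` stores exactly those sufficient statistics, which keeps
likelihood evaluation O(#distinct depths × #states) regardless of colony
size.

Posterior estimation uses adaptive multiple importance sampling with
uniform priors (μ ~ U[0,1]; α uniform on the simplex, i.e. Dirichlet(1)).
Draws are proposed in unconstrained coordinates (logit μ, additive
log-ratios of α) from a defensive mixture of the prior (weight 0.2) and a
Gaussian refitted each round to the weighted draws so far (covariance
inflated 1.5× and ridge-regularized); final weights are computed against
the pooled mixture of all round proposals so every round's draws are
usable, and all weight arithmetic is in log space. A random-walk Metropolis
sampler is kept as an independent cross-check and the two agree on
simulated data within Monte-Carlo error. With no data the sampler returns
the prior (mean μ = 0.5), a property the tests assert.

Problem sizes used in the tests: 50 colonies × depth 5 × L = 10 for the
three-state regime (recovery within ±0.03 on μ) and one 1024-cell colony ×
L = 2943 at μ = 0.0005 for the low-rate two-state regime (recovery within
a factor of 2).

## Feature space and labels

For a pair of barcodes the feature vector counts, per unit, the unordered
pair of observed categories. With m = |S|+1 categories there are m(m+1)/2
bins; for the three-state recorder these are the conventional F1 (both
ground), F2/F3 (single edit), F4/F6 (same edit) and F5 (different edits).
The unordered-pair count was chosen over a factorial-growth predictor set:
the named F-classes pool both orders of each mixed pair, and the pooled
definition extends consistently to any |S|. `feature_pair_map` exposes the
bin-to-category-pair map for audit. Feature vectors always sum to L and are
symmetric in the pair — both are property-tested.

A pair of leaves is *positive at level t* when the ancestors t edges above
each leaf exist and coincide: t = 1 are siblings, t = 2 share a
grandparent. Positivity is monotone in t (once related, always related
higher up); leaves shallower than t cannot share a level-t ancestor and are
labeled negative. At level d every pair of a depth-d colony meets at the
root, so the deepest informative level for a corpus of maximum depth d is
d−1; `train_pipeline` trains levels 1..d−1 and the assembly reuses the
deepest model beyond that.

## Per-level classifiers

One LightGBM binary ensemble per level, configured to the classic
gradient-boosting-machine recipe: logistic loss, up to 1000 trees with the
iteration count chosen by 5-fold cross-validated loss (early stopping after
50 stagnant rounds), per-tree depth cap 10, minimum 5 observations per
leaf, fitted on a random half of the rows, shrinkage 0.1 (the conventional
default where unstated). The depth cap maps an interaction-depth-style
parameter onto LightGBM's `max_depth`; the mapping is recorded in each
model's JSON metadata. Training is single-threaded and deterministic given
the seed.

Interpretation follows standard practice: relative importance is
split-count based (how often a feature is selected), normalized to
percentages (gain-based importance is reported alongside); ICE curves sweep
one feature over an observed-value grid per observation, and the partial
dependence curve is their pointwise mean — an identity the tests assert to
1e-10. On simulated three-state data all six features carry nonzero
importance and the F3 partial dependence at level 1 trends downward
(mismatched editing argues against siblinghood), matching the biological
reading.

## Tree assembly

Reconstruction starts from singleton clusters at level 1. At each level the
level-t model scores every cell pair once; the probability between two
clusters is the maximum over cross-member pairs. Cluster pairs are sorted
by probability (ties broken lexicographically on each pair's smallest then
largest member id, making the assembly deterministic) and merged greedily —
each cluster at most once per level — while the probability exceeds the
level's cutoff. Unmerged clusters pass through; the level then increments,
reusing the deepest trained model beyond the trained range. If a level
commits no merge while more than two clusters remain, the single best pair
is force-merged so the assembly always terminates; the final one or two
clusters are joined at the root. The output is strictly binary with
exactly 2N−1 nodes.

**Merge cutoffs.** Two estimators are provided. `estimate_level_thresholds`
picks the per-level Youden-optimal (sensitivity + specificity − 1) cutoff
on validation pair predictions, defaulting to 0.5 with no validation data.
The pipeline default, `tune_merge_threshold`, instead grid-searches a
shared cutoff over {0, 0.05, ..., 0.7} minimizing the mean RF score of
reconstructed *validation* colonies (a held-out slice of the training set;
test colonies are never consulted). The reconstruction-based tuner exists
because pair-classification optimality is the wrong target for merge
commitment: on complete binary colonies every cluster truly merges at every
level, so any cutoff that blocks merges displaces attachment heights and
propagates errors upward, and the tuner duly selects low cutoffs there. On
incomplete or noisy colonies the grid can select conservative cutoffs
instead.

## Maximum-parsimony baseline

The starting tree is UPGMA (average linkage, lowest-index tie-breaking for
determinism) on barcode Hamming distances. Tree scoring is Fitch small
parsimony — per unit, the bottom-up union/intersection count of state-set
changes, states unordered — implemented over bitmask arrays and compiled
with numba; it equals the exhaustive minimum over internal labelings on
small trees (tested to 8 leaves). The search is a parsimony ratchet with a
minimum of 100 iterations: per iteration, characters are reweighted by a
multinomial bootstrap, the tree is hill-climbed by first-improvement
nearest-neighbor interchange on the weighted score and then on the original
score, and the result is kept only when it strictly improves. NNI-only
search (no SPR) is a deliberate simplification that keeps the baseline fast
and honest at colony scale; on 6-leaf instances the ratchet reaches the
exhaustive 105-topology optimum in ≥90% of seeded runs. Parsimony scores
are invariant to rooting, so rooted trees are scored as-is.

## Tree-comparison scores

All four scores are symmetric, 0 on identical trees and normalized to
[0, 1].

- **RF**: unrooted nontrivial bipartitions; the symmetric-difference count
  divided by the total split count of both trees (2(n−3) for two binary
  trees).
- **TRP**: fraction of leaf triples whose rooted triplet topology differs
  (the cherry pair is the pair with the strictly deepest LCA; a tie means
  unresolved). Exact enumeration to 512 leaves, seeded uniform subsampling
  (100 000 triples) above.
- **QRT**: quartets are resolved by the four-point condition on topological
  distances (root degree-2 subdivision cannot flip or tie a resolved
  pairing). With counts s/d/r1/r2/u of same/different/one-side-resolved/
  both-unresolved statuses over Q quartets, the score is
  (2d + r1 + r2)/(2Q): a resolved-versus-unresolved disagreement counts as
  half. This yields 0 for identical binary trees and exactly 0.5 for a
  binary tree against the star. Exact to 100 leaves, subsampled above.
- **CLI**: each nontrivial split contributes its bipartition entropy; splits
  of the two trees are matched one-to-one by maximum-weight assignment on
  pairwise mutual information (from the 2×2 leaf-overlap table), and the
  distance (H1 + H2 − 2S)/(H1 + H2) is the unshared fraction of total split
  information. The H1+H2 normalization reproduces the worked-example range
  (all four scores in [0.53, 0.60] for the across-clade swap), so no
  alternative denominator was needed. Values within 1e-12 of 0 are snapped
  to 0 to absorb floating-point residue on shared splits.

TRP is deliberately the only rooted metric: it alone detects a clade
re-attached at the wrong height (worked example: 16/56 = 0.29 with the
other three scores at 0).

## Benchmarks

`run_benchmark` simulates training and test colonies from one
configuration, trains the per-level models (tuning the merge cutoff on the
last 10% of training colonies), reconstructs every test colony with the ML
assembly and/or the parsimony baseline, scores all four metrics against the
ground truth, and reports per-method means plus the relative improvement
100·(mean_parsimony − mean_ml)/mean_parsimony together with per-tree paired
differences. Results carry the seed and a config hash for provenance; a
fixed seed reproduces the table bitwise.

The reduced shallow configuration used throughout (2 edit states, L = 20,
200 training / 30 test colonies) is the package's standard demonstration
size: at it, the ML assembly beats parsimony on mean RF (0.167 vs 0.209 at
seed 0, direction stable across seeds) and CLI, while parsimony keeps an
edge on TRP/QRT at this training scale — rooted attachment heights are
where the ML assembly pays for threshold-blocked or premature merges, and
more training trees narrow that gap.

## What the simulations do and do not show

The generator produces complete, synchronous, noise-free colonies: no cell
death, no asynchronous division, no barcode dropout or readout error, and
every leaf sampled. Passing tests therefore demonstrate correctness of the
algorithms and the direction of the ML-vs-parsimony comparison under ideal
recorder conditions; they do not quantify robustness to readout noise,
missing cells or colony heterogeneity, which real datasets exhibit.
Reconstruction quality on real recorders is expected to be lower and the
ML margin smaller.

## Degenerate inputs and numerical conventions

Identical barcodes give flat probability landscapes: assembly and UPGMA
fall back to documented lexicographic/lowest-index tie rules, so outputs
remain deterministic. Likelihoods of impossible observations are −∞ rather
than errors; importance weights are normalized in log space and an
all-underflow situation raises an explicit error. Scores raise on
mismatched leaf sets, and the minimum leaf counts are 4 (RF, CLI, QRT) and
3 (TRP). Strict-improvement acceptance (tolerance 1e-9) in the ratchet
prevents cycling on plateaus.
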