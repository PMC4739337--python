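# Methods

## The problem

Random-forest variable importance measures (VIMs) are widely used to rank
features — genes, clinical covariates, spectral bins — by their relevance to
a classification outcome. Two measures dominate practice:

* **MDA** (mean decrease accuracy): for each tree, permute one feature's
  values among the tree's out-of-bag (OOB) samples and record the drop in
  correct OOB predictions divided by the OOB size; average over trees.
* **MDG** (mean decrease Gini): sum the weighted Gini-impurity decreases of
  every split that uses the feature within a tree; average over trees.

Both are stochastic even on *fixed* data with *fixed* hyper-parameters:
bagging and per-node feature subsampling (mtry) randomize every tree, and
MDA adds a third randomness source, the OOB permutations. The
self-consistence of a VIM across repeated runs that differ only in this
internal randomness is its **intrinsic stability**; it bounds from above
whatever stability one can observe under data perturbation or parameter
variation, and it is the quantity this package measures.

## Importance measures as implemented

A forest is `ntree` CART-style trees (Gini criterion, grown to purity, no
depth limit), each trained on a bootstrap resample of size n drawn by the
package's own RNG, with `mtry` candidate features sampled uniformly at each
split. The tree learner is scikit-learn's `DecisionTreeClassifier`; the
bagging layer, OOB bookkeeping, and both VIMs are implemented here, with
per-tree bootstrap membership recorded exactly. (Fitting many small trees
is dominated by scikit-learn's per-fit input revalidation, so the forest
fitter converts the matrix to float32 once and skips the redundant label
re-check — the tree construction itself is unchanged.)

MDA is the *unscaled* mean of per-tree accuracy decreases (no standard-error
normalization), with one fresh permutation per (tree, feature) drawn from a
sub-stream of the run seed, and the permutation confined to the tree's OOB
samples. Trees with an empty OOB set are skipped and the mean is taken over
the remaining trees. A feature that no split of a tree uses cannot change
that tree's predictions, so its contribution is exactly zero — this makes
the "constant feature has importance exactly 0" invariant exact rather than
statistical.

MDG is defined textually as the total impurity decrease attributable to a
feature, averaged over all trees. (A sometimes-printed variant,
(1/n_dot)[1 − Σ_k Gini^k], is not a decrease and is dimensionally
inconsistent; it is not implemented.) The per-node decrease is weighted by
the fraction of bootstrap samples reaching the node, so per-tree decreases
sum to a dimensionless total and the conservation identity
Σ_j MDG(j) = mean per-tree total decrease holds to float precision.

OOB accuracy predicts each sample by majority vote of only the trees whose
OOB set contains it, excludes samples covered by no tree, and breaks vote
ties toward the lowest class label.

## Stability indices

Given k runs, every index is evaluated on all k(k−1)/2 unordered pairs and
reported as the list, its mean, and its sample variance (n−1 denominator).
Rankings order features by descending score with ties broken by ascending
feature id.

* **Spearman**: 1 − 6 Σ (p_g − p_h)² / (d(d²−1)) on the two rank vectors.
* **Jaccard** (prefix-averaged): mean over j = 1..d−1 of
  |top-j(g) ∩ top-j(h)| / |top-j(g) ∪ top-j(h)|.
* **Kuncheva**: mean over j of (r_j − j²/d) / (j − j²/d), where r_j is the
  top-j intersection size — the overlap corrected for what chance alone
  would produce. Its expectation over independent random rankings is 0
  (verified by Monte Carlo in the tests).
* **MARD**: mean over features of |s_g − s_h| / (|s_g + s_h| / 2) on the raw
  scores; 0 means identical score vectors.

**Truncation.** When d > cap (default 100), only the top-cap features of
each ranking enter the evaluation. The prefix sums of Jaccard and Kuncheva
simply stop at cap. Spearman and MARD need a common feature set, which the
two truncated lists do not provide; the package takes the **union** of the
two top-cap sets (so between cap and 2·cap features enter), densely
re-ranks each ranking within that union for Spearman, and compares raw
scores over the union for MARD. An intersection mode exists for Spearman
behind a flag. The union choice preserves all evidence either run considers
important; the intersection discards exactly the disagreements the index is
supposed to measure.

**Kuncheva chance term.** The chance-overlap term j²/d uses the *full*
dimensionality d even under truncation (configurable): the probability that
two independent rankings place the same feature in a top-j prefix is
governed by the whole feature pool, not by the evaluation cap.

**MARD edge cases.** MDA scores can be negative or zero. Terms whose scores
sum to zero contribute 0 (a warning counts the cases where the scores also
differ), and the denominator uses |s_g + s_h|/2 so the index stays
non-negative when a sum is negative. MARD is a quantity designed for
positive repeated measurements; for MDA at small ntree, where many scores
hover around zero with either sign, its values are dominated by these
near-cancellations and should be read with care — MDG, whose scores are
non-negative by construction, is the cleaner companion for MARD.

**Notched-box summaries.** Median, quartiles, whiskers at the most extreme
values within 1.5·IQR of the hinges, and a notch of half-width
(3.14/2)·IQR/√n — the conventional approximate median-comparison interval.
Notches larger than the box simply signal skewed, small-n distributions.

## Protocols

All randomness flows from a single `master_seed` through a deterministic
seed tree (protocol → arm → run, via `numpy.random.SeedSequence` spawn
keys). Every run's seed is stored in the result's provenance, and replaying
the stored seeds reproduces any reported number bit-exactly.

* **Intrinsic**: k_runs (default 10) repeated VIM runs on identical data and
  configuration; k-way stability of the rankings (Spearman, Jaccard,
  Kuncheva) and scores (MARD).
* **Data perturbation**: the samples are randomly partitioned into `folds`
  (default 10) equal parts (unstratified by default, matching a plain random
  partition; a stratified mode exists for fragile class balances). One VIM
  run per fold-complement training set; k-way stability across the folds'
  outputs. A training set that loses a class entirely raises an error naming
  the fold. The nested intrinsic arm repeats k_runs runs on *each* training
  set, computes per-training-set stability, and averages the means over
  folds — per-point stability first, then the average, never the pooled
  pairs.
* **Parameter variation**: one VIM run per grid point — ntree over
  (50 … 50000) by default with mtry at its default, or mtry over the
  symbols one/dwdef/def/updef (1, half, √d, 1.5·√d, rounded and clamped to
  [1, d]) at fixed ntree — with the same nested per-point intrinsic arm.
  The protocol logic is grid-agnostic; experiments in the test suite use
  scaled-down grids.

The default configuration for non-grid protocols is ntree = 20000 with
mtry = √d, the conventional converged setting; every experiment shipped in
the tests scales this down (see below).

## Indicator correlations

Five per-dataset indicators — #feature, #sample, #class, forest OOB
accuracy, and the composite ratio #feature/#sample (the degree of
high-dimension/small-sample) — are correlated with per-dataset intrinsic
stability means using Spearman (average-rank ties) or Pearson coefficients.
p-values use the two-sided t-approximation on n−2 degrees of freedom for
both coefficients, with significance read at 95% confidence; a Monte-Carlo
permutation option exists for very small n. A packaged table of the shape
characteristics of 19 widely used UCI/GEMS benchmarks supports the
reference analysis of indicator dependence (its #feature/#sample Spearman
correlation is −0.63, p ≈ 0.0038, reproduced in the tests).

## Synthetic data

The generator emulates the two regimes in which VIM stability is studied:
low-dimensional/large-sample tabular data (p ≈ 8–60, n ≈ 200–8000) and
high-dimensional/small-sample gene-expression-like data (p in the
thousands, n in the tens, few informative features, redundant correlated
copies, many noise features). Classes are balanced to ±1 sample. Class
means for the informative block are drawn at random, centred, given unit
across-class spread per feature, scaled by a geometric strength-decay
profile (so features have a well-ordered importance hierarchy, as real data
does), and finally rescaled so the *minimum* pairwise distance between
class means equals `class_separation` in units of the noise standard
deviation — separation 4 makes even the closest class pair nearly
separable, mirroring the high OOB accuracies of the benchmark shapes the
named fixtures copy (`yeast_like`: p=8, n=1484, C=10; `srbct_like`: p=2308,
n=83, C=4; etc.). Redundant copies add Gaussian noise calibrated to a
target within-block correlation (default 0.7) against the parent column's
realized spread.

What the generator does **not** emulate: batch effects, missingness,
heavy-tailed expression distributions, label noise, and correlation
structure beyond the explicit redundant blocks. Passing tests therefore
demonstrate the machinery and the qualitative mechanisms (convergence in
ntree, ratio-driven instability, arm ordering) on clean Gaussian analogues,
not quantitative agreement with any real benchmark.

## Experiment scales used in the tests

The shipped experiments are scaled to run on a single CPU in minutes; the
qualitative claims they check are scale-robust, and the protocol code is
size-agnostic.

* Convergence in ntree: yeast-shaped data at n = 200 (p = 8, C = 10), grid
  (50, 200, 1000, 5000), 10 runs per point, 10 replicate suites, MDG.
* Ratio sweep: 12 datasets with p rising 10 → 1500 as n falls 600 → 30,
  ntree = 150, 10 runs, MDG.
* Arm ordering: p = 20, n = 200, C = 3 data; perturbation at ntree = 100
  with 10 folds and 5 nested runs over 20 replicates; ntree-variation grid
  (50 … 2000) with the intrinsic comparator taken at the converged end of
  the grid, where a box-to-box spread comparison is meaningful.
* MDA, whose permutations triple the runtime, is exercised in the unit
  tests and invariants; the protocol-level experiments use MDG, which
  shares two of the three randomness sources.

## Numerical choices and degenerate inputs

* Ranking ties break by ascending feature id; OOB vote ties toward the
  lowest class label — both deterministic.
* Tiny negative per-node impurity decreases from float round-off are
  clamped to 0.
* Single-feature rankings make every rank index undefined (division by
  d−1): an error, not a sentinel value.
* Sample variance of a single pairwise value (k = 2) is reported as 0.
* `resolve_mtry` uses Python's round (banker's) and clamps to [1, d];
  d = 1 collapses every symbol to 1.
* Perfect correlations short-circuit the t-approximation (p set to the
  smallest positive float rather than 0, keeping p in (0, 1]).

## Known limitations

* MDA on datasets with thousands of features is slow at large ntree; the
  per-tree cost is proportional to the number of *distinct features used by
  that tree's splits*, not d, which keeps high-dimensional/small-n cases
  tractable but large-n cases expensive.
* The union rule for truncated Spearman/MARD is one defensible choice among
  several (intersection, first-list anchoring); results at d > cap depend
  mildly on it, which is why the mode is exposed.
* Indicator correlations on suites where several indicators co-vary (as in
  any realistic benchmark collection) measure association, not causation;
  the ratio sweep holds separation and class count fixed precisely to
  isolate the ratio's effect.
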