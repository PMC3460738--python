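# Methods

This note records the models, conventions and numerical choices behind
`thyrotex`, and what results on its synthetic cohorts do and do not show.

## Image model and preprocessing

All analysis operates on 2-D 8-bit brightness matrices (0–255), indexed
in matrix convention (row m, column n).  DICOM pixel data deeper than 8
bits are mapped onto 0–255 by a linear min–max rescale before any feature
is computed, because every feature below is defined on the 8-bit scale.
The 3×3 median filter uses edge replication at the borders; replication
keeps the output range inside the input range, which is what the
range-bound features (w2, w4) assume.  The ROI is supplied explicitly
(`top,left,height,width`, 1-based inclusive origin) — automatic lobe
detection is out of scope — and every feature sees only the cropped,
median-filtered ROI.  ROIs must be at least 8×8, the smallest size on
which all ten features are defined.

## The ten features

* **w(1) — mean power spectrum.** `Σ|DFT(L)|²/(M·N)` with the
  unnormalized forward DFT.  By Parseval's identity this equals
  `Σ L(m,n)²`, which the test suite uses as a transform-free oracle.
  Note the consequence: the literal formula grows with overall image
  energy, so a bright homogeneous ROI scores *higher* than a dark
  heterogeneous one — the feature is a brightness-energy measure, not a
  pure frequency-content measure.  The literal definition is kept.
* **w(2) — regional-minima mean.** Regional minima are maximal
  8-connected equal-valued plateaus whose every outside neighbour is
  strictly brighter; w2 averages the brightness over all minima pixels.
  8-connectivity with plateau support is the standard morphological
  default.  A constant image is a single plateau with no outside
  neighbours, hence one all-image minimum (w2 = the constant); this case
  is handled explicitly because the underlying scikit-image routine
  treats constant images as having no minima.  `reduce="min"` switches
  to the literal darkest minimum instead of the mean.
* **w(3) — smoothness.** Brightness is scaled to [0, 1] by division by
  255 and σ is the population standard deviation; w3 = 1 − 1/(1+σ²).
  The unit scale makes homogeneous images score ≈ 0 (on the raw 0–255
  scale almost any image would saturate towards 1).
* **w(4) — filtered histogram minimum.** 256-bin histogram; bins with
  counts ≤ 20 % of the modal count are treated as noise; w4 is the
  smallest surviving gray *level* (argmin over the index, not over the
  count).  Gray levels 0–255 all participate, so genuinely black pixels
  are representable; sparse dark outliers are suppressed, which is the
  intended difference from w(2).
* **w(5), w(6) — GLCM centroid and area.** Raw counts of horizontal
  neighbour pairs (offset (0, +1), 256 levels): an Ms×Ns ROI yields
  exactly Ms·(Ns−1) pairs.  The matrix is symmetrized by adding its
  transpose, normalized to sum to 1, and binarized with a strict
  threshold at 0.1 × the normalized maximum.  The centroid uses 1-based
  matrix indices (gray level + 1), so a constant image of level g gives
  w5 = √2·(g+1) and w6 = 1.  The 0.1 threshold is exposed as a
  parameter.
* **w(7)–w(10) — quadtree block fractions.**  The ROI is first adjusted
  to a power-of-two square by *central cropping* to the largest inscribed
  2ᵏ×2ᵏ block — padding was rejected because it fabricates homogeneous
  area and inflates the large-block features.  A block is split into four
  equal squares while its brightness range exceeds 10 % of the full
  dynamic range (0.10·255 = 25.5, a fixed absolute threshold rather than
  a per-block relative one, so thresholds are comparable across images);
  leaves are homogeneous blocks or single pixels, and the block sides
  tile the square exactly (Σ counts(s)·s² = S², a tested invariant).
  The features are `counts(s)·s/(Ms·Ns)` for s = 1, 2, 4, 8 with the
  block *side* in the numerator — kept exactly in this published form
  although it is not an area fraction, so the four values need not sum
  to anything in particular.

## ROC screening

Decision thresholds sit at `min + k·(max−min)/steps`, k = 0..steps
(11 thresholds at the default 10 % increments).  The classification
direction per feature is unstated a priori, so it is auto-oriented to
make AUC ≥ 0.5 and the orientation (±1) is reported.  Before trapezoid
integration the curve is anchored at (0,0) and (1,1); without the
anchors a constant feature would not reduce to the chance diagonal
(AUC = 0.5).  The trapezoidal AUC equals the Mann–Whitney pair-counting
statistic whenever the threshold grid resolves every distinct feature
value (verified in tests on lattice-valued data); on continuous data a
coarse grid can miss ROC corners, so dense grids should be used when the
exact U-statistic is wanted.

## CART, pruning, metrics

Trees are grown greedily on Gini impurity with no minimum node size,
stopping at pure nodes or when no split strictly decreases impurity.
Tie-breaks are deterministic: lowest feature index, then lowest
threshold; thresholds are midpoints of consecutive sorted values; a
tied leaf predicts disease (favouring sensitivity in a screening
setting).  Note one corner: because zero-gain splits are not taken, an
XOR-like configuration yields a single-leaf tree rather than a grown
tree with deferred gains.

Pruning computes the classic weakest-link cost-complexity sequence
(misclassification cost; all nodes at the minimal g collapsed per step,
giving nested subtrees with nondecreasing α) and applies the 1-SE rule:
the smallest subtree whose estimated cost is within one standard error
of the minimum.  Two cost estimators are provided:

* **10-fold stratified cross-validation** on the learning split
  (default for a single model fit).  Candidate complexities are the
  geometric midpoints √(αₖαₖ₊₁); the SE is the binomial standard error
  √(p(1−p)/n) of the pooled CV error.
* **Validation-split error** (default inside the subset sweep, where a
  held-out validation third exists and ~10⁵ prunings per significance
  run make CV prohibitive); SE is the binomial standard error on the
  validation split.

Metrics follow the standard identities (TPR, FPR, ACC, TNR, PPV, NPV,
FDR, error % = 100·(FN+FP)/total); zero denominators yield NaN with no
exception.

## Subset sweep and significance

Feature subsets are coded as 10-bit integers 1..1023, bit i−1 ⇔ w(i)
(64 = {w7}, 524 = {w3, w4, w10}).  One sweep draws a random stratified
learn/valid/test split (each class dealt into near-equal thirds) and
fits, for every code, a full tree and its pruned counterpart — 2 trees
per code, 2046 fitted trees, matching the 2·2¹⁰ accounting with the
empty code excluded (it cannot yield a tree).  The optimal subset of a
sweep minimises the pruned-tree test error, ties broken by fewer
terminal nodes, then lower code; this is the formal version of picking
the lowest-left point of the error-versus-size Pareto front
(`pareto_front` exposes the front itself).

`significance` repeats the sweep R times with child seeds drawn from the
master seed and tallies: the share of each feature among winning subsets
(summing to 100 %), the share of each feature among the 1022 disqualified
configurations per repetition (summing to 100 %), the pairwise
co-occurrence percentages among disqualified configurations (symmetric;
the diagonal holds single-feature percentages), and the histogram of
winning codes.  R defaults to 50 — large enough for a planted informative
feature to rank first reliably, small enough to run in about a minute on
one CPU; R is configurable upward.

**A selection-bias caveat** that matters for interpreting the winner:
the optimal subset is the minimum of test error over 1023 candidates
evaluated on the *same* test split, so its reported test accuracy is
upward-biased (winner's curse).  On signal-free cohorts the selected
model's in-selection accuracy averages far above chance (~0.83 measured
at test n = 16), while its accuracy on a freshly generated cohort is
indistinguishable from 0.5.  The null-calibration test therefore
evaluates the selected model on selection-independent data; any skill
claim for a sweep-selected subset should do the same.

## Synthetic cohorts

The generator is a statistical test phantom for the two-class contrast,
not a physical B-mode simulation.  A texture is a base level μ times
multiplicative Gaussian speckle (1 + σₛ·N(0,1)), plus a Poisson(λ)
number of bright elliptical follicle blobs and, for the disease class,
bright line segments mimicking fibrosis, clamped to 0–255.  Defaults:

| parameter | control | Hashimoto-like |
|---|---|---|
| mean echogenicity μ | 160 | 125 |
| speckle dispersion σₛ | 0.12 | 0.20 |
| follicle rate λ | 3 | 6 |
| fibrosis streaks | 0 | 2 |
| ROI side | 64 | 64 |

A per-subject brightness random effect (SD 15) correlates the four views
of one subject and gives the classes a moderate overlap (subject-level
standardized gap ≈ 2.3) rather than trivial separability — a difficulty
comparable to accuracies reported for clinical cohorts of this kind.
The default cohort design is 29 control + 65 case subjects × 4 views
(left/right × transverse/longitudinal) = 376 images; views carry no
signal unless `view_offsets` is set.

What the generator does **not** model: the physics of speckle (Rayleigh
statistics, depth-dependent attenuation, focal zones), scanner post-
processing, anatomical context (capsule, carotid, isthmus), nodules, or
decibel-calibrated echogenicity.  Passing tests on these cohorts
demonstrate that the pipeline's machinery is correct and that it
recovers planted statistical structure; they say nothing about clinical
discrimination performance, which depends on real images.

## Problem sizes

Test-suite and acceptance-script runs use desk-scale sizes chosen as the
package's own defaults: 376-image cohorts for end-to-end runs, 100-image
cohorts for sweep-cardinality checks, R = 50 significance repetitions
(tallying ~10⁵ fitted trees), 20-seed Monte-Carlo loops for calibration
properties.  Exhaustive oracle comparisons (regional minima) cover all
3-level 3×3 images and sampled 4×4 images.

## Known limitations

* w(1) is dominated by mean brightness (Parseval), so it largely
  duplicates echogenicity rather than isolating periodicity.
* The GLCM uses 256 gray levels at offset (0, +1) only; no multi-offset
  or quantized variants.
* Greedy growth without zero-gain splits cannot represent XOR-style
  interactions that require look-ahead.
* Validation-based pruning inside the sweep makes each code's pruned
  tree depend on a single validation third; with small cohorts the
  pruned sizes are noisy across seeds.
* `quadtree_decompose` recurses in Python; on full 614×816 frames with
  strong speckle it can visit ~10⁵ blocks and take seconds per image.
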