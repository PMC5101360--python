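# Methods

This note documents the models, conventions and numerical choices behind
`colonyqc`, and what the synthetic data does and does not establish.

## The classification model

The task is three-class grading of stem-cell colony images (bad /
semigood / good). Multiclass classification is reduced to binary
problems with error-correcting output codes: a coding matrix
`CM ∈ {−1, 0, +1}^{M×Nc}` whose rows are class codewords and whose
columns are dichotomies. Training a column fits one binary learner on
exactly the rows of the classes with a nonzero entry, relabelled to that
entry's sign. Prediction collects the Nc hard outputs into a codeword
`s` and selects `argmin_i D(i)` with the Hamming binary loss
`ℓ(z) = (1 − sign z)/2`:

* `loss_weighted` (default): `D(i) = Σ_j |CM_ij| ℓ(CM_ij s_j) / Σ_j |CM_ij|`.
  This is the normalisation used by the MATLAB-toolbox lineage of ECOC
  implementations; since learners emit hard ±1 labels, it equals the
  Hamming distance over a row's nonzero positions divided by their count.
* `hamming`: the unnormalised sum over nonzero positions.
* `performance_weighted`: `D(i) = Σ_j w_ij ℓ(CM_ij s_j)` with `w_ij`
  proportional to learner j's training accuracy on class i, rows
  normalised to sum 1 — the class-accuracy-weighted reading of
  "loss-weighted decoding" found in the decoding literature. Both
  readings are implemented because the source material does not
  disambiguate; the normalised form is the default.

Ties in `argmin D` go to the smallest row index. Codewords are hard
labels only: the learners expose no margins, matching the pairing of the
Hamming loss with hard outputs.

### Coding designs

One-vs-all (M columns), one-vs-one (M(M−1)/2; pairs (i, j), i < j,
enumerated lexicographically, class i on the +1 side), ordinal (M−1;
column t puts classes 1..t on −1), ternary complete
((3^M − 2^(M+1) + 1)/2) and binary complete (2^(M−1) − 1). The complete
designs enumerate all admissible columns, canonicalise sign so each
column's first nonzero entry is −1, deduplicate, and sort
lexicographically; for M = 3 the ternary-complete output is emitted in
the conventional published column order via a fixed permutation/sign
map. All constructions are deterministic.

One structural caveat: for M = 2 the one-vs-all design necessarily emits
two mutually negated columns. The validator reports this honestly; it is
an accepted redundancy of that degenerate configuration, not a bug.

Class rows follow sorted label order by default (`bad < good <
semigood`, which coincides with the published table layout); the order
is a parameter because the ordinal design is order-sensitive and the
natural quality gradient (bad → semigood → good) is a defensible
alternative a user may pass explicitly.

## Binary learners

**k-NN** — seven distances (Chebyshev, cityblock, correlation, cosine,
Euclidean, standardized Euclidean, Spearman; the correlation-type
measures are one minus the respective similarity, Spearman on average
ranks) and three vote weightings (equal, 1/d, 1/d²). Conventions chosen
for determinism: the standardized Euclidean scale is the per-feature
sample std (n−1 denominator) of the training subset, frozen at fit time;
under inverse weightings a zero-distance neighbour restricts the vote to
the zero-distance neighbours with equal weight (avoids division by
zero); a tied vote falls back to the single nearest neighbour's label,
then −1. Distance ties are broken by training-row order (stable sort).

**Discriminant analysis** — Gaussian class models scored by
`δ_c(x) = −½(x−μ_c)ᵀΣ_c⁻(x−μ_c) − ½ logdet⁺(Σ_c) + log π_c` with
empirical priors by default. Linear variants pool one covariance across
classes ((n−2)-denominator pooling of the two class covariances),
quadratic variants estimate one per class; `diag_*` keeps only the
diagonal; `pseudo_*` uses the Moore–Penrose pseudoinverse and
pseudo-determinant (product of eigenvalues above the tolerance
`d · eps · λ_max`), so rank-deficient covariances — routine when the
feature dimension exceeds a class size, as with 128-dimensional
descriptors and ~40-member classes — still fit. The plain variants raise
a covariance-not-positive-definite error in that regime, which the
experiment grid records as a structured skip: an unevaluable
configuration is itself a result.

**Naive Bayes** — per-feature class densities, normal or kernel-smoothed
with Gaussian φ(u), box ½·1[|u|≤1], Epanechnikov ¾(1−u²)·1[|u|≤1] or
triangle (1−|u|)·1[|u|≤1] kernels. The bandwidth follows the
normal-reference (Silverman) rule `h = 1.06 σ̂ n^{−1/5}` per class and
feature, overridable by an explicit value, since no bandwidth is pinned
by the source material. Zero densities under compactly supported kernels
are floored at the smallest positive double before taking logs.

**CART** — greedy Gini tree, thresholds at midpoints of consecutive
distinct sorted values, ties between equal-gain splits resolved to the
lowest feature index then lowest threshold. Impure nodes accept
zero-gain splits (standard CART behaviour; required to work through
locally uninformative structure such as an XOR pattern); growth stops at
pure nodes, the optional depth limit, or when no admissible split
remains. Leaves predict their majority label, exact ties → −1.

## Features and preprocessing

Images are reduced to a mean SIFT descriptor: detect keypoints with
scikit-image's SIFT backend (default settings), average the p × 128
descriptor matrix column-wise. Descriptor values are deterministic for a
fixed backend but differ across SIFT implementations, so the contract
pins per-backend determinism, not cross-backend equality; the backend is
a configuration key.

Preprocessing standardises each column to zero mean and unit sample
variance, then min–max rescales to exactly [−1, 1] using the observed
post-standardisation extremes. Columns with zero variance (or whose
standardised values collapse to a single float) map to all-zeros. By
default preprocessing is computed on the whole table before
cross-validation — the order the study states — which leaks fold
statistics; a leakage-free per-fold mode (`per_fold_preprocess=True`)
refits the transform on each training fold and applies it to the
held-out row.

## Evaluation

Plain LOO for parameter-free learners. Nested LOO for k-NN: for each
outer fold, a full inner LOO over the n−1 training rows scores every
candidate k; the k with the highest inner multiclass accuracy (ties →
smallest k) is shared by all binary learners of the ensemble and used to
predict the held-out row. The result records the selected k per outer
fold — it legitimately varies across folds — and the full inner-accuracy
table. Reported measures: per-class TP and TPR = TP/n_c, overall
ACC = Σ TP / n, and the confusion matrix; rendered percentages are
rounded half-up to one decimal, matching the result-table format.

The default grid is 4 designs × (21 k-NN + 3 discriminant variants
(linear, diagonal linear, pseudo-quadratic) + tree + 5 naive Bayes) =
120 configurations, k-NN under nested LOO and the rest under LOO.

## Synthetic data

The study's 173-image dataset is private, so the package ships two
generators that define its test conditions.

*Feature tables* draw isotropic Gaussians: class means sit pairwise
`separation · std` apart along distinct coordinate axes; defaults are
the published composition 41 bad / 74 good / 58 semigood, 128
dimensions, unit std, separation 3 (a moderately hard problem — chosen
so default tables are neither trivial nor hopeless). At separation 10
the classes are essentially disjoint and nearest-neighbour LOO recovers
100% accuracy for typical seeds; note that in 128 dimensions the
within/between distance gap at separation 10 is only about three
standard deviations of the χ²-concentration noise, so isolated
misclassifications (accuracy 99.4–99.6%) occur for a minority of seeds.
At separation 0 there is no signal and a prior-driven classifier's LOO
accuracy approaches the majority-class frequency; local classifiers such
as 1-NN instead approach Σ_c p_c², so the no-signal check uses the
ordinal design with diagonal LDA in low dimension, where the class prior
dominates.

*Images* render an elliptical colony (radius ≈ 0.35 of the frame, ±8%
seeded jitter) on a feeder-cell-textured background (bandpass-filtered
noise, amplitude 0.08 by default — a knob, because feeder texture is a
known descriptor contaminant). The edge is a sigmoid of the normalised
elliptical radius with width `0.008 + 0.18·(1 − sharpness)`; the
interior is 0.72 ± 0.35·heterogeneity × smooth noise; "three-dimensional
structures" are bright Gaussian bumps (σ ≈ 6% of the frame) placed
inside 0.55 of the colony radius. Class presets (sharpness,
heterogeneity, blobs): good (0.9, 0.1, 0), semigood (0.8, 0.5, 0), bad
(0.3, 0.6, 3) — fixed constants expressing the published grading
criteria, not fitted to any data.

What passing tests on these generators show: the pipeline's mechanics
(feature extraction width, preprocessing span, ensemble training and
decoding, fold bookkeeping) and parameter recovery under known signal.
What they do not show: performance on real colony morphology,
illumination drift across imaging sessions, manual segmentation effects,
or feeder-cell intrusion into colonies — the renderer's texture is a
caricature, and real semigood/bad boundaries are far subtler than the
presets.

## Problem sizes

The test suite and the acceptance script scale the expensive protocols
down: k-NN oracle checks use ≥500 problems with n ≤ 30, d ≤ 5; nested
LOO runs on tables of 18–48 rows with small k grids; the no-signal check
uses a 24/42/34 composition in 3 dimensions over 10 seeds; the
end-to-end image check renders 20 images per class at 256 × 256 and
evaluates one-vs-all 1-NN under LOO. The full 173 × 128 / 120-setup grid
with k up to 23 runs through exactly the same code paths and is
available via `colonyqc grid`, at minutes-to-hours cost depending on the
learner family.

## Known limitations

* No soft/score decoding (hard codewords only), no sparse/dense random
  or discriminant coding designs, no tree pruning or surrogate splits.
* SIFT keypoint internals are delegated; descriptor values are not
  comparable across backends.
* The performance-weighted decoder defines weights only on nonzero
  coding entries; classes absent from a column receive zero weight there.
* Metrics are confined to TP/TPR/ACC and the confusion matrix — the
  measures the report format needs; ROC/AUC/F1 are binary-oriented and
  out of scope.
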