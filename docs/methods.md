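# Methods

## The ensemble importance

Given a table of n_s samples with numeric features X₁…X_p and a binary class
y ∈ {0,1}, each selected scorer m produces a raw importance vector r⁽ᵐ⁾ on
its own scale. Raw vectors are mapped to the common interval [0, 1/n] (n =
number of selected methods) by

  s⁽ᵐ⁾ = clip(r⁽ᵐ⁾, 0, ∞) / max(clip(r⁽ᵐ⁾, 0, ∞)) · 1/n,

and the ensemble importance of feature j is Σₘ s⁽ᵐ⁾ⱼ ∈ [0, 1]. Two
properties drove the choice of *max-scaling* over min-max shifting: a raw
score of exactly zero (an FCBF-eliminated feature, a feature no tree ever
split on) must remain exactly zero after normalization, and ratios between
positive scores are conserved exactly, so the normalization changes units,
not the relative geometry of the importances. Negative raw values — possible
for permutation importances of pure-noise features — are clipped to 0, the
scale's semantic floor ("no importance"); consequently "a constant feature
scores the minimum" is a statement about the normalized scale, where it is
exact, not the raw scale, where a noise feature may dip below 0. An
all-non-positive raw vector maps to all zeros rather than dividing by zero.

Ranking ties are broken by input column order (stable sort). The default
selection rule for the "selected subset" is *above-mean*: features with
ensemble score strictly greater than the mean score; `top_k` and a fixed
threshold are available where a size budget or cutoff is wanted.

## The eight scorers

**median.** Two-sided Mann-Whitney U test between the class-1 and class-0
values of a feature; raw importance 1 − p. For combined group size ≤ 12 with
no ties the p-value is exact (full enumeration of the U distribution,
p = min(1, 2·min(P(U≤u), P(U≥u)))); otherwise the normal approximation with
tie and continuity correction is used. Pairwise-complete values only; a
feature with one class entirely missing scores 0 with a warning.

**pearson / spearman.** First the fast correlation-based filter: features
are visited in decreasing |corr(Xⱼ, y)| (ties by column order) and kept iff
their |pairwise correlation| with every already-kept feature is ≤
`cor_threshold`. Eliminated features score exactly 0. Kept features score
1 − p of the two-sided correlation test against the class (t reference;
Spearman on average ranks), computed on pairwise-complete pairs. Undefined
correlations (constant feature, < 3 complete pairs) count as 0.

**logreg.** Features are Z-transformed (per-column mean 0, sd 1 with the
n−1 denominator, zero-variance columns to all-zero), missing entries imputed
to 0 (= the post-standardization column mean), and a maximum-likelihood
logistic regression is fit; the importance is |βⱼ|. When p ≥ n or the fit
shows separation (some |β| > 15 on the standardized scale) the model is
refit with a small ridge penalty (λ = 10⁻⁴), which keeps the scorer defined
on wide or separable tables; a warning records the fallback.

**rf_mdi, rf_error, cf_error, cf_auc.** Forests of CART trees (Gini splits,
mtry = ⌊√p⌋ candidate features per split, grown to purity, 100 trees per
forest by default). rf_* variants bag with replacement; cf_* variants — an
approximation of conditional-forest resampling — subsample without
replacement at fraction 0.632, which removes the bootstrap-induced
preference for high-cardinality features that the conditional-forest
literature targets; conditional-inference split tests themselves are *not*
implemented, a deliberate simplification that should be kept in mind when
comparing against true conditional forests. `rf_mdi` is the mean decrease
in Gini impurity (split impurity decrease weighted by the fraction of
samples reaching the node, summed per feature, averaged over trees).
The permutation variants follow Breiman: per tree, evaluate the error rate
(or, for `cf_auc`, the AUC) on the tree's out-of-bag samples, permute one
feature's OOB values once, re-evaluate; the importance is the mean over
trees of the metric degradation. One permutation per tree-feature pair
suffices because each scorer is itself averaged over `runs` independent
forests (default 100); trees with empty or single-class OOB sets are
skipped with a warning. Missing values are median-imputed inside the forest
scorers only. Per-variant seeds are derived from the run seed through a
fixed-order seed tree, so a scorer's output does not depend on which other
scorers were selected.

## Preprocessing

Features whose missing fraction *strictly exceeds* `na_threshold` (default
0.2) are dropped before scoring — "more than" is implemented as a strict
inequality, so a feature at exactly the threshold survives. Remaining
missing values are handled per scorer as described above rather than by a
global imputation. Constant features and strong class imbalance (minority
< 10%) are flagged, not repaired. Rows with a missing class label are
rejected at parse time.

## Evaluation suite

**LOOCV + DeLong.** Leave-one-out cross-validation of the logistic model on
the selected features and, separately, on all features: each fold
standardizes on its n−1 training samples only (no leakage) and predicts the
held-out sample's class-1 probability; a single-class training fold predicts
the training class rate. The two per-sample score vectors give paired ROC
curves (midrank tie convention; the stored AUC is the trapezoidal integral
of the curve and equals U/(n₁n₀)); DeLong's test with the
structural-component covariance estimate (midrank formulation) yields a
two-sided p-value for equal AUCs, with p = 1 by convention when the variance
of the AUC difference is 0 (e.g. identical score vectors).

**Class-permutation test.** Labels are permuted `p_num` times (default 100);
each permutation reruns the LOOCV on the fixed, already-selected subset
(selection is *not* repeated inside the permutation loop). The permuted
AUCs are compared with the observed AUC by a one-sided one-sample t-test;
small p means the observed model beats its own chance distribution. A known
property to be aware of: LOOCV with per-fold refitting is pessimistically
biased under the null — holding out a positive sample lowers the training
class rate and hence that sample's predicted probability — so the permuted
AUCs centre somewhat *below* 0.5 (≈0.41 at n = 100 in our measurements,
approaching 0.5 as n grows). This makes the test conservative in the
direction of declaring significance (the null distribution sits lower), and
it means the permuted AUC mean should not be read as an estimate of 0.5.

**Importance stability.** `bs_num` rounds (default 100) each draw
⌊`bs_percentage`·n⌋ samples (default 90%) without replacement, stratified so
both classes survive, and rerun the full ensemble. Reported are the
per-feature sample variances of the ensemble scores across rounds (computed
shifted by the first round, so bit-identical rounds give exactly 0) and the
Jaccard index |∩Sᵢ|/|∪Sᵢ| of the selected subsets (undefined and an error
when every round selects nothing). Subsampling — rather than resampling with
replacement — keeps every round's rows distinct, which the LOOCV-style
refitting inside each round's logistic scorer requires.

## Synthetic data

The generator emulates the selector's input shape: Bernoulli(class_balance)
labels; informative features N(0,1) + Δ·y with a common effect size Δ in sd
units (default 1.5, a separation at which single methods are good but not
perfect, so ensembling is visibly useful); correlated features
ρ·parent + √(1−ρ²)·N(0,1) cycling over informative parents; independent
N(0,1) noise; missing values completely at random at `na_rate`. It does
**not** emulate heavy tails, feature-dependent missingness, batch structure
or nonlinear/interaction-only signal — passing recovery tests on this
generator therefore demonstrates correctness of the pipeline's mechanics
and its behaviour under Gaussian mean-shift signal, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The test suite exercises the full recovery setting at n = 200 samples with
5 informative + 45 noise features over 100 seeds, with forests scaled to
10 runs × 50 trees — variance of the averaged forest importances at that
depth is already far below the informative/noise score gap. DeLong
calibration uses 1000 null replicates at n = 500. Logistic fits converge at
tol 10⁻⁸ (≤100 iterations before the ridge fallback). Importance tables are
serialized at 12 significant digits and round-trip within 10⁻¹⁰. All
randomness flows from a single integer seed through `numpy` seed sequences;
runs restricted to the deterministic scorers (median, correlations, logreg)
are seed-independent.

## Known limitations

Binary targets only; categorical features must be dummy-encoded upstream.
The cf_* variants approximate conditional forests by their resampling
scheme only (see above). The correlation scorers' p-value-based importance
saturates near 1 for any strong feature at large n, compressing differences
among top features within those two methods (the forest and regression
scorers keep separating them). The above-mean selection rule can return an
empty set when all scores are equal; the library then warns and reports no
selection rather than guessing.
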