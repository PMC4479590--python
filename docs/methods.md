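# Methods

## Movement metrics

A trajectory is a strictly time-ordered sequence of planar fixes for one
animal at a nominal interval (the modal time step, robust to isolated gaps).
Each consecutive fix pair (i, i+1) yields one interval record:

* **step distance** — Euclidean distance in metres between the two fixes;
* **turning angle** — at fix i, the absolute angular deviation of the
  direction of step i→i+1 from the direction of step i−1→i, in degrees in
  [0, 180]. The sign of the turn is discarded: every statistic downstream
  (class separation, the stationary-angle artefact) concerns only the
  magnitude. The first interval of a trajectory, any interval adjacent to a
  zero-length step, and any interval following an irregular-duration interval
  has an undefined angle.

Intervals whose duration deviates from nominal by more than ±10% are excluded
with a warning rather than interpolated; with modern receivers fix failure is
rare, so this costs little data and avoids fabricating positions. Coordinates
may be supplied in planar metres or as lon/lat degrees; the latter are
projected by a local equirectangular approximation around the data centroid
(x = R·cos(lat₀)·Δlon, y = R·Δlat, R = 6 371 008.8 m), which is accurate to
well under 0.1% at the ≤ 2 km extents of paddock-scale tracking and is checked
against a haversine oracle in the tests. No datum/projection machinery is
pulled in for this; beyond ~10 km or near the poles the approximation is
refused rather than silently degraded.

Lower-frequency datasets are derived from high-frequency ones by keeping every
k-th fix starting at index 0 (a 12 s series from 2 s logging with k = 6);
phase 0 is fixed for determinism since no phase is canonical.

## Coupling observations to intervals

Visual observations are bouts: (animal, start, end, behaviour) with behaviours
from a fixed ethogram of mutually exclusive classes (Walking, Foraging,
Standing, Lying, plus rare classes excluded from analysis). Only time under
simultaneous observation is usable, so an interval not fully covered by
observation is never labelled.

* **pure mode** (training data): the interval is labelled iff a single
  behaviour covers ≥ 99% of its duration. The 1% tolerance absorbs the 1 s
  resolution of observation logs against exact GPS timestamps.
* **dominant mode** (mixed-interval evaluation): a fully observed interval is
  labelled with the behaviour occupying the most time; exact ties are dropped
  rather than broken arbitrarily.

Samples with an undefined angle are dropped from classifier datasets (the
trees use both features), which is also why angle-based group tests run on
slightly fewer samples than distance-based ones. Lying and Standing — both
stationary, hence kinematically indistinguishable in GPS — can be pooled as
`Resting` after labelling; pooling rewrites labels only and conserves counts
and features.

## The classifier

A from-scratch CART over the two features:

* **Growth**: recursive binary splitting by Gini impurity decrease, candidate
  thresholds at midpoints between consecutive distinct sorted feature values,
  exhaustive over both features. No depth limit; the only guard is a minimum
  leaf size (default 5). Determinism is guaranteed by fixed tie rules:
  distance before angle, then the smaller threshold; leaf prediction ties go
  to the first class in class order; routing is "≤ goes left".
* **Pruning**: minimal cost-complexity (weakest-link). Each step collapses the
  internal node(s) with the smallest per-leaf increase in training
  misclassification error, producing a nested subtree ladder from the full
  reference tree down to the root, with non-decreasing α.
* **Size selection**: repeated stratified k-fold cross-validation (defaults
  k = 10, 10 repeats) estimates misclassification risk for every tree size
  realised on the ladder (other sizes are unreachable by pruning). Within a
  fold, a tree is grown on the k−1 training folds and its own ladder is pruned
  to each candidate size; risk is averaged over folds and repeats, and the
  reported sd is across repeat means. The chosen size is the lowest-risk one
  whose pruned tree still predicts **every** required class at some leaf
  (ties → fewer leaves); if no size covers all classes, the best-covered
  lowest-risk size is used with a warning. This coverage condition is what
  keeps a rare-but-real behaviour in the model even when dropping it would
  lower raw risk.
* Misclassification costs are equal and class priors empirical despite heavy
  imbalance — deliberately, since the operational question is raw percent
  correct per observed class, and the consequences (a rarely predicted
  minority class like Standing) are reported, not hidden.

Folds are stratified by class because minority classes can have fewer samples
than folds; such classes simply appear in a subset of folds, with a warning.
The cross-validation convention is the standard one (train on k−1 folds, test
on the held-out fold).

The model surface follows the statsmodels idiom: `BehaviourTreeModel` (data +
settings) with `from_dataframe`/`from_dataset` constructors, whose `fit()`
returns `BehaviourTreeResults` holding the pruned tree, reference tree,
pruning ladder, risk curve, selected size, and methods `predict`, `confusion`,
`rules` (plain-text decision rules, one per leaf, with training class counts)
and `summary`.

## Validation statistics

Confusion matrices are oriented rows = observed, columns = predicted, with
integer percent-correct values (half-up rounding) per observed class and
overall; a class never observed has an *undefined* (not 0) per-class value.
The overall value is the trace over the total, equivalently the row-weighted
mean of the per-class values.

Group differences in distances and angles between behaviours are tested with a
permutation ANOVA: the classical one-way F statistic referenced against its
label-permutation distribution, because the class sample sizes are wildly
unequal and the variances heterogeneous. With n_perm random permutations the
p-value uses the add-one estimator (x+1)/(n_perm+1); when the number of
distinct group assignments is at most n_perm the null is enumerated exactly
and p is the exact exceedance fraction (e.g. two completely separated groups
of three: 2 of the 20 assignments reach the observed infinite F, p = 0.10).
Pairwise post-hocs multiply raw p-values by the number of unordered pairs
(Bonferroni), capped at 1. Repeated-measures structure (the same animals
contribute many intervals) is ignored by the test, a known conservative
simplification. Sequential/early-stopping permutation schemes are not used;
fixed n_perm keeps results reproducible from the seed.

## The synthetic-study generator

The generator emulates a day of cattle-like tracking with ground truth, so the
pipeline can be validated without field data.

* **Schedule**: behaviours alternate (uniform over the other behaviours);
  bout durations are log-normal. Defaults (median, log-sd 0.5): Foraging
  20 min, Lying 10 min, Standing 2 min, Walking 2 min. These make grazing
  dominate the daytime budget (~60% of pure 1-min intervals), as it does for
  pastured cattle, with walking transits and standing pauses of a couple of
  minutes — long enough that fully aligned pure 1-minute walking intervals
  exist at all.
* **Kinematics** (correlated random walk at base_dt = 2 s; truncated-normal
  speed ≥ 0, wrapped-normal heading increments): Walking 1.0 ± 0.2 m/s,
  heading sd 10°/step; Foraging 0.25 ± 0.08 m/s, heading sd 15°/step;
  Standing and Lying exactly stationary. Foraging's parameters put its
  1-minute displacement (~13 m rms) clearly above the open-ground error floor
  (~3 m per step pair at σ = 2.1 m) but far below Walking (~60 m), yielding
  the characteristic Walking ≫ Foraging ≫ Resting ordering of 1-min distances;
  at 2 s intervals the same parameters put every behaviour's true step inside
  the error floor, which is exactly why high-rate classification fails.
* **Positional error**: iid bivariate Gaussian per fix, sd σ per axis
  (defaults 2.1 m "open field", 6.0 m "forest", the reported accuracies of
  wildlife collars in those conditions). No HDOP/satellite-geometry model and
  no fix failure: modern receivers achieved 100% fix success in the field data
  this emulates.
* **Receiver smoothing**: optional second-order exponential smoothing (two
  cascaded EWMA passes per axis, parameter α; α = 1 disables). One EWMA pass
  was considered and rejected on first principles: the increments of any
  AR(1)-filtered stationary error remain negatively correlated (the fraction
  of stationary turning angles above 90° is exactly 1/2 + α/4 ≥ 1/2), so no
  single-pass position smoother can reproduce the empirically observed
  *suppression* of high turning angles at short fix intervals. The cascade is
  the discrete analogue of a critically damped constant-velocity tracking
  filter — the kind actually embedded in receivers — whose smoothed error
  drifts with persistent velocity, making consecutive steps positively
  correlated (fraction ≈ 0.28 at α = 0.3, ≈ 0.19 at α = 0.2, strictly
  decreasing in α).

With no smoothing, the stationary-behaviour angle distribution matches the
iid-position null exactly: the dot product of consecutive steps is a 1:3
mixture of χ² variables, so P(angle > 90°) = P(F₂,₂ < 3) = **3/4**. Simulation
and an independent iid-triple Monte-Carlo oracle agree with this closed form
to ±0.003 at n = 10⁵. (A tempting but wrong shortcut — the sign probability of
a single coordinate product, 2/3 — is not the 2-D answer.) Real stationary
data show somewhat lower fractions (~54–64%) because real error is temporally
autocorrelated and partially smoothed; the generator reproduces that regime
through α.

What the generator does **not** emulate: temporally autocorrelated raw error
(smoothing is the only dependence mechanism), multi-animal interaction,
habitat-dependent behaviour differences (e.g. browsing recorded as foraging),
observation gaps within the day, and fix failure. Passing end-to-end tests
therefore demonstrate that the pipeline recovers behaviour when its
statistical assumptions hold at realistic noise levels — not that any real
deployment will reach the same accuracy.

## Problem sizes and numerical choices

The bundled experiments use a 9 h day at 1-minute fixes (≈ 460–500 pure
intervals) for the open-field and forest conditions, and a 1 h session at 2 s
fixes (≈ 1 800 intervals) for the high-rate condition, with five replicate
seeds — comparable to the field sample sizes the workflow is designed for, and
small enough that the whole validation suite runs in well under a minute per
condition on one CPU. Monte-Carlo checks of the angle null use 10⁵ simulated
triples (binomial se ≈ 0.0014); permutation tests default to 999 permutations
(199 in the type-I calibration, 1 000 replicates). Gini gains below 10⁻¹²
count as zero; equal-gain splits, equal-risk sizes and equidistant pruning
targets all resolve to the smaller/first option so that identical inputs and
seeds reproduce every artifact byte-for-byte.

## Known limitations

* Only two features; no speed/heading/net-displacement metrics, no
  accelerometer fusion, no time-of-day covariate.
* No surrogate splits or in-tree missing-value handling: undefined angles are
  excluded before fitting, matching how the statistics treat them.
* The permutation ANOVA ignores the repeated-measures structure of multiple
  intervals per animal.
* The equirectangular projection is for local extents only (≤ ~10 km,
  |lat| < 89°).
* Lying and Standing are indistinguishable by construction in GPS-only data;
  the package reports this honestly (near-zero Standing recovery) and offers
  `Resting` pooling as the remedy.
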