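# steptree

Infer animal behaviour from high-frequency GPS fixes using step distances,
turning angles and pruned CART decision trees.

## The problem

GNSS collars record an animal's position every few seconds to minutes. Between
two consecutive fixes the animal covered some **step distance** *d* (Euclidean,
metres) and turned by some **turning angle** θ at the first fix — the absolute
deviation of the outgoing step direction from the incoming one, in [0°, 180°]
(0° = straight on, 180° = full reversal). Different behaviours leave different
signatures in (*d*, θ): travelling is fast and straight, grazing/foraging is
slow and tortuous but steadily displacing, and resting is stationary — except
that positional error makes a stationary animal's signal "jump" around the true
location, producing spuriously large distances and turning angles concentrated
towards 180°.

`steptree` implements the full classification workflow for such data, aimed at
movement ecologists and livestock researchers with simultaneous visual
observations of behaviour:

1. **Coupling** — each between-fix interval is labelled from an observation log
   (an ethogram of mutually exclusive behaviours): *pure* intervals, in which a
   single behaviour spans the whole interval, form the training data; mixed
   intervals can be labelled with their *dominant* (most-time) behaviour.
2. **Classification** — a CART tree over (*d*, θ): Gini-impurity growth without
   a depth limit, minimal cost-complexity ("weakest link") pruning, and tree
   size chosen by repeated stratified 10-fold cross-validation as the
   lowest-risk size that still predicts every behaviour class.
3. **Validation** — half-split training/validation, confusion matrices with
   per-class and overall percent correct, and permutation ANOVA (one-way F
   against its label-permutation null, with Bonferroni-corrected pairwise
   post-hocs) for group differences in the movement metrics.
4. **Simulation** — a seeded generator of behaviour-annotated GPS studies:
   log-normal behaviour bouts, correlated-random-walk kinematics per behaviour,
   iid Gaussian positional error (e.g. 2.1 m in the open, 6 m under canopy) and
   an optional velocity-tracking receiver smoother, so the whole pipeline is
   testable end to end with known ground truth.

## Worked example

Simulate a day of open-pasture tracking at 1-minute fixes with 2.1 m positional
error, train, prune and validate:

```python
import steptree as st
from steptree.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(sim=st.open_field_config(seed=1), split_seed=1, cv_seed=1)
report = run_experiment(cfg)
print(report.summary())
```

```
Behaviour classification tree (CART)
============================================
samples:            240
classes:            Foraging, Lying, Standing, Walking
features:           distance_m, angle_deg
min samples/leaf:   5
cross-validation:   10-fold x 10 repeats (seed 1)
reference tree:     12 terminal nodes
selected size:      7 terminal nodes
pruned tree size:   7 terminal nodes
training accuracy:  93.8%

risk curve (cross-validated misclassification):
  n_terminal  risk_mean  risk_sd
           1     0.3458   0.0000
           2     0.1504   0.0031
           3     0.1046   0.0031
           7     0.0838   0.0036  <- selected
          12     0.0867   0.0047

training overall correct:   94%
validation overall correct: 92%
  validation Foraging: 97%
  validation Lying: 92%
  validation Standing: 0%
  validation Walking: 100%
mixed-interval dominant-behaviour correct: 55%
```

Reading this: 240 pure 1-minute intervals trained the tree; the unrestricted
reference tree had 12 leaves, and cross-validation picked 7 as the smallest
risk (8.4% estimated misclassification) still predicting all four behaviours.
On the held-out half, 92% of intervals are classified correctly. Walking is
perfectly recovered (large distances), Foraging and Lying separate on the
distance threshold around 6.6 m, and Standing — kinematically identical to
Lying — is essentially never recovered, which is why the two are usually pooled
as `Resting` (`pooling=st.RESTING_POOL`). The first exported rule shows the
interpretable output:

```
IF distance_m <= 6.577 AND distance_m <= 5.214 THEN Lying (Foraging=1, Lying=50, Standing=6, Walking=0)
...
IF distance_m > 6.577 AND distance_m > 34.354 THEN Walking (...)
```

The same objects work on real files: `read_fix_table` / `read_observation_log`
accept CSVs (planar metres or lon/lat, ISO-8601 or epoch-second timestamps),
and `ExperimentConfig(fix_table=..., observation_log=...)` runs the identical
pipeline. A `steptree` CLI exposes the stages (`simulate`, `metrics`, `couple`,
`train`, `evaluate`, `classify-mixed`, `run-all`).

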