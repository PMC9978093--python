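# Methods

`gazefeit` reimplements, as a tested pipeline on synthetic data, an
eye-movement analysis of facial-emotion-identification trials: gaze streams
recorded at 120 Hz while participants (controls, adults with ASD or
schizophrenia, children with ASD) viewed face stimuli for 5 s each are
reduced to trial-level features or gaze heat maps, classified per trial, and
aggregated per participant with a stimulus-weighted random forest, evaluated
by nested leave-one-participant-out (LOPO) cross-validation.

## Event detection and trial features

Gaze samples carry both eyes' normalized coordinates plus validity flags.
The two eyes are combined into a cyclopean point (mean when both valid, the
valid eye otherwise); a sample with neither eye is invalid.

Events come from the minimal velocity-threshold (I-VT) classifier: the
angular velocity between a sample and the previous valid sample (bridging
invalid gaps up to 75 ms, a vendor-typical default) is compared with a
100 deg/s cutoff; *strictly exceeding* the cutoff makes the sample a saccade,
anything else a fixation.  The first valid sample of a run inherits its
successor's label.  No minimum fixation duration, merging, or smoothing is
applied — the reduced pipeline keeps the classifier transparent and exactly
testable.  Angular velocity needs physical geometry: the default display
model is a 24-inch 16:9 panel (531 x 299 mm) viewed from 650 mm; velocities
scale with this assumption and the geometry is configurable.

Per trial (600 samples) the features are:

* fixation-sample counts inside each area of interest (eyes up to the
  eyebrows, nose, mouth; per-stimulus polygons, boundary inclusive) and
  anywhere — *sample* counts, not event counts: at 120 Hz x 5 s the observed
  magnitudes (hundreds out of 600) are only consistent with sample counts;
* the saccade count (maximal runs of saccade-labeled samples);
* scan-path length: mean Euclidean displacement per consecutive valid-valid
  sample pair, in normalized screen units (distances are summed within valid
  runs and divided by the number of pairs; an all-stationary or all-invalid
  trial scores 0).

Trials are excluded from the statistics stage when the scan-path length is 0
or fewer than 40% of samples are valid.  The classification stage uses all
trials (training-set sizes of 630/651 trials match complete 21- and
32-trial banks).

## Heat maps and model inputs

A binary hit map at native resolution (1920 x 1080) marks every visited
pixel, is blurred with a normalized Gaussian (sigma = 10 px, reflective
boundary), stacked with the grayscale stimulus image, center-cropped to the
largest square around the face bounding box (side rounded down to a multiple
of 34 so downsampling is exact block averaging), area-downsampled to
34 x 34, and min-max scaled per channel (a constant channel maps to 0).
Blurring happens before downscaling because sigma in pixels is only
meaningful at native resolution.  Two separate channels (stimulus, heat map)
let the classifier relate gaze retention to facial regions.  For sparse hit
maps the blur adds one truncated Gaussian patch per hit with reflect-folded
borders; this agrees with full separable convolution to ~1e-9 and is two
orders of magnitude faster, and the scipy filter remains the independent
oracle in the tests.

## Trial classifiers

* Baseline: an MLP on (total fixation-sample count, saccade count, scan-path
  length), three hidden layers of 5 ReLU units, 2 output logits.  Features
  are z-scored with training-fold statistics only; constant features map
  to 0.
* CNN: two 3x3 convolutions (8 then 16 filters), each followed by ReLU and
  2x2 max pooling, then a fully connected layer with 2 logits (~2.9k
  parameters — deliberately small for ~630-trial training sets).

Both train with minibatch Adam on softmax cross-entropy for at most 300
epochs, stopping early when the validation loss has not improved for 15
epochs and restoring the best-validation weights.  The validation split is
participant-level 8:2, stratified by class.  The learning rate is selected by
an inner leave-one-participant-out grid search (default grid {1e-2, 1e-3,
1e-4}; ties go to the smallest rate; the inner loop can be capped for
runtime).  Trials inherit their participant's diagnosis as the label; the
per-trial problem is deliberately noisy and is resolved by aggregation.
The networks are implemented in numpy (exact im2col gradients, seeded He
initialization), which keeps training bit-reproducible under a fixed seed.

Two protocol details guard against leave-one-out artifacts on no-signal
data.  A LOPO fold's training set is tilted against the held-out class by
construction (removing a disorder participant leaves a control majority); a
trial model fitted on such data drifts toward the training majority, and
majority voting amplifies that drift into systematically wrong participant
labels — below-chance "null" accuracy.  Training therefore (a) subsamples
majority-class trials to the minority count per fold (deterministic under
seed; the source study likewise under-sampled participants to align groups)
and (b) weights the loss by inverse class frequency for any residual
imbalance.  With both in place, null-cohort LOPO accuracy sits inside the
95% binomial band around the majority rate (verified in the acceptance
suite).

## Aggregation

A participant's per-trial predictions are ordered by stimulus face number
(presentation order was randomized; importances are reported per face) into
a 21- or 32-length binary vector.  Hard voting takes the majority (an exact
tie on even-length vectors goes to the disorder class).  The weighted
aggregator fits a random forest (500 trees, Gini, unlimited depth, fixed
seed) on the training participants' vectors; its feature importances,
averaged across cross-validation folds, read out which stimuli carry the
group signal.  By default the forest trains on in-sample first-stage
predictions (re-applying the fold's trial model to its own training trials,
mirroring the source procedure); an out-of-fold mode is available because
in-sample vectors are optimistic.  A forest with no splits (degenerate
input) reports uniform importances and majority-class predictions.

## Evaluation

Nested LOPO: each fold holds one participant out of *every* fitted component
(scaler, learning-rate selection, trial model, forest), classifies the
held-out trials, and aggregates both ways.  Folds whose training data lose a
class are recorded as failures and scored as errors so totals always
reconcile.  Metrics are exact rational evaluations of accuracy,
sensitivity = TP/(TP+FN), and specificity = TN/(TN+FP), with the disorder
group positive; zero denominators are flagged rather than raised.
Performance is compared with chance by the exact binomial test (two-sided by
doubling the smaller tail, capped at 1); the chance rate defaults to 0.5
with the majority-class rate selectable.

## Group statistics

Per emotion and feature, group means +- SD are tabulated over trials (the
analysis unit is the trial) and contrasts are tested with Welch's
unequal-variance t-test (two-sided, Welch-Satterthwaite df).  P-values are
Benjamini-Hochberg adjusted; the default family is all emotion x group-pair
tests within one feature, and the family definition is recorded in the
output because the choice is not canonical.

## Synthetic cohorts

The clinical recordings are unreleased, so a generator produces cohorts with
the group x emotion structure the analysis assumes.  A trial alternates
fixation epochs with single-sample saccadic transitions: each epoch targets
eyes/nose/mouth/other with per-emotion dwell probabilities, anchors
uniformly inside the region, and jitters samples isotropically (sd 0.004
normalized units, small enough that jitter stays below the I-VT cutoff);
transitions overshoot the next anchor by a per-group amplitude, which
controls scan-path length independently of AOI layout; samples drop out
i.i.d. (both eyes) at a per-group rate, and one eye is occasionally missing
from valid samples.

Calibration inverts the closed-form feature expectations: dwell fractions
are set so expected eye/mouth fixation-sample counts match the published
group x emotion means, and the saccade amplitude is solved from the
group-mean scan-path target given the saccade rate (control 8/s, ASD 10/s,
Sz 13/s) and a Monte-Carlo estimate of mean anchor distance.  Child profiles
are calibrated the same way from the children's table, giving small group
contrasts concentrated in anger-trial eye dwell.  `expected_features`
recomputes these semi-analytic expectations for any profile, and the tests
require simulated cell means to land within a declared 20% of them.

Two deliberate non-realisms: the published scan-path magnitudes (0.05-0.22
normalized units per 8.3 ms sample) imply far larger and more frequent jumps
than physiological saccades, and the generator reproduces the magnitudes,
not plausible kinematics; and invalid samples are i.i.d. rather than bursty,
because the pipeline's validity filter only thresholds the valid fraction.
The generator also omits pupillometry, blinks as events, head movement, and
photographic stimuli (schematic grayscale faces with matching AOI geometry
stand in for the copyrighted photographs).  Passing tests therefore show the
*machinery* behaves correctly on data with the assumed statistical
structure, not that the published effect sizes are recoverable from real
recordings.

## Problem sizes in the test and acceptance runs

The suite exercises the full published cohort geometry (15-16 participants
per group, 21/32 trials each) but shortens training where the check cannot
depend on convergence: the null-calibration check pools 10 seeded cohorts
per variant with few-epoch training (no variant can extract signal from a
null cohort regardless of epochs), and the weighting-benefit check runs the
baseline trial model over 10 seeded cohorts.  The acceptance script uses 2-3
seeded cohorts per quantity and 200 simulated trials per calibration cell.

## Known limitations

* Whether the study counted fixation events or samples, the exact
  multiple-comparison family, the heat-map scaling, and the first-stage
  predictions fed to the forest (in-sample vs out-of-fold) are all
  unstated in the source; the choices above are documented defaults, and
  the forest mode is switchable.
* The generator's per-emotion saccade-rate override used to construct
  signal-confined cohorts is an experimental knob, not an estimate of any
  real process.
* The binomial p-value reported for the schizophrenia contrast in the source
  (p = 0.052 at 20/31 correct) is not reproducible under either chance-rate
  convention (0.5 gives 0.15, majority rate gives larger); it is therefore
  not asserted anywhere in the suite.
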