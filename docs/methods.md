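# Methods

## Event model and segmentation

A log line is `date time sensor_id value [activity-marker]`, whitespace
separated; the writer emits tabs and millisecond-precision timestamps so
parse∘write is the identity. Out-of-order timestamps are tolerated with
a warning and a stable sort (clock jitter is routine in deployments);
malformed lines fail with their line number rather than being dropped
silently.

Segmentation walks the stream keeping the set of open activity spans.
Every event — including the marker events themselves, which in
CASAS-style logs are ordinary sensor readings carrying an annotation —
is credited to **every** span open at its timestamp; events outside all
spans are discarded. Activities can interleave (answering the phone
while cooking), and crediting an event to each open span is the only
attribution that needs no extra assumptions; it is flagged here because
other conventions (nearest span, most-recent start) would change counts
on interleaved logs. Unpaired or nested-duplicate markers are errors,
not warnings: a mispaired log silently corrupts every downstream count.
Completeness (did the participant finish the whole scripted session) is
session-level knowledge supplied by the caller or simulator, never
inferred from the stream.

The matrix builder derives its width from the supplied sensor
inventory (sorted lexicographically — the canonical feature order used
everywhere downstream) plus three summary columns: `duration_s`,
`unique_sensor_events`, `completeness`. The count of features is
therefore inventory-specific, not hard-coded.

## PKFS

Support of feature *s* in class *x* is the number of the class's
instances where *s* is strictly positive; precedence is the class-total
raw frequency. `U_i` (default 2 in the experiments here) floors the
support; `U_f` (default 7) caps the per-class selection; ties break on
canonical feature order for determinism. Precedence is deliberately
computed **before** rescaling: rescaling is a per-feature affine map
fitted for the classifiers' benefit, and comparing rescaled values
across features would distort the frequency ordering the method is
defined by. Summary features compete with sensor features on equal
terms; because they are large-magnitude totals, duration and the
distinct-sensor count top every class's ranking, which is why the
default per-class budget is planted-signal size + 2 in the recovery
experiments.

Rescaling maps each feature to [0, 1] by the training-fold min/max,
clamping held-out values and sending zero-range features to 0. The
scaler, the selection, and the comparator selectors are all fitted on
training rows only; a test verifies that perturbing held-out rows
leaves the fitted fold transform bit-identical.

`tune_thresholds` grid-searches (`U_f`, `U_i`) by mean fold-wise macro
F under the full pipeline, breaking ties toward smaller `U_f` (fewer
features) then larger `U_i` (stronger support evidence).

## SKFS

The 13 statistics are computed row-wise on each instance's selected
vector, in union order, on the rescaled values (matching the pipeline
order: scale, select, summarize). Conventions, chosen once and tested
against an independent naive implementation to 1e-9:

- population moments; kurtosis is excess; skewness and kurtosis are 0
  for constant vectors;
- quantiles (median, IQR) by linear interpolation;
- crossing rates are sign changes per step (an exact zero is not a
  crossing), so they lie in [0, 1];
- "pairwise correlation" is the lag-1 autocorrelation of the ordered
  vector — a single row admits no feature-pair correlation, so the
  sequential reading is the one that yields a per-instance number; 0
  when variance is 0;
- spectral entropy is the Shannon entropy (natural log) of the DFT
  power spectrum of the mean-centered vector normalized to sum 1, and 0
  when all power vanishes.

The sequence statistics (derivative, crossings, autocorrelation,
spectral entropy) are only meaningful relative to an ordering of the
feature vector; the canonical lexicographic order makes them
deterministic, and that convention is a documented stand-in rather than
a claim about any particular ordering being physically meaningful.

## Evaluation

Stratified 3-fold cross-validation (stratification keeps the small
dementia cohort represented in every fold) with the fold-hygiene above.
Metrics come from the pooled confusion matrix: per class, TP is the
diagonal entry, FN the rest of its row, FP the rest of its column;
0/0 ratios are defined as 0 (a never-predicted class has precision 0).
Micro-averaged F equals accuracy in single-label multiclass problems,
and F is invariant to transposing the matrix — both asserted on random
matrices as consistency checks.

Classifier roster: random forest (100 trees), 1-nearest-neighbor
(unweighted), polynomial-kernel SVM (C = 1, tol 1e-3), decision tree,
Gaussian naive Bayes — standard scikit-learn implementations behind a
string spec. Comparator selectors: PCA retaining 95% variance by
default (with variance 1.0 the component count is min(n−1, features) —
the mean-centering rank bound); information gain = mutual information
between each feature and the target; mRMR = greedy
mutual-information-difference. Both MI selectors discretize continuous
columns by equal-frequency binning with 5 bins — the MI estimate is
binning-dependent, so the binning is fixed for reproducibility — and
take `m` features, with `m` set to the PKFS union size for a
like-for-like comparison.

## Explanations

The local report fits a ridge surrogate to the model's predicted-class
probability (one-vs-rest for multiclass) over Gaussian perturbations of
the instance (default sigma 0.25 — one quarter of the [0, 1] feature
scale the pipeline produces; explaining a model trained on raw counts
requires a correspondingly larger scale), weighted by an exponential
distance kernel, all under a fixed seed. Reported weights are the
surrogate's coefficients, sorted by magnitude; a positive weight
supports the predicted class.

Global importance is permutation importance: the mean drop in model
score over seeded shuffles of one column. Two caveats shape its use and
its tests: it must be measured on held-out data (a memorizing forest
shows no drop on its own training rows), and it is only informative
away from accuracy saturation — with a strongly redundant signal
(five interchangeable planted sensors per class) permuting any single
column barely moves the score. The importance tests therefore run at a
moderate planted elevation (rate 2.0 against background 0.4) with a
participant-level train/held-out split.

## Simulator

The generator emulates a scripted cognitive-assessment session in a
62-sensor home (30 motion, 10 door, 8 item, 5 temperature, 5 light, 3
utility, 1 power). Defaults mirror the study population it stands in
for: 65 healthy and 14 dementia participants, 8 activities each, one
instance per participant-activity (632 rows). Per activity span:

- duration is log-normal (median 120 s + 30 s per activity index,
  ln-dispersion 0.2);
- each sensor fires Poisson-many times at uniform times in the span;
  rates are defined per *nominal* activity duration and scaled by the
  realized span length (time-integrated Poisson: slower runs accumulate
  proportionally more triggers, aborted runs fewer);
- each activity has 5 disjoint planted informative sensors at rate 8
  against background 0.4 — the ground truth for recovery experiments;
- off-task "wander" events hit uniformly random sensors at a
  per-minute rate, inside spans and in the 60 s gaps between them
  (gap events fall outside every span and must be discarded by the
  segmenter).

The dementia profile stretches duration medians 1.5×, multiplies the
wander rate 5× (2.5 vs 0.5 events/min), aborts spans early with
probability 0.3 (vs 0.02), and re-triggers in-activity sensors 1.5×
(the repetition/confusion signature of impaired task execution). These
defaults put the cohorts in the strongly-separable regime the method
is meant for; `matched_cohort_config` equalizes all four behavioral
parameters as a null control (cohort classification then collapses to
chance), and `null_config` removes the planted signal and the duration
differences as the activity-recognition null.

What the simulator does **not** model: indoor-movement physics and
sensor adjacency, diurnal structure, sensor failures or missing data,
inter-activity interleaving (the segmenter supports it; the generator
does not emit it by default), and participant-level random effects
beyond the cohort profiles. Passing recovery and recognition tests on
this generator therefore demonstrates the pipeline's correctness and
its behavior under a known count-based generative model — not
performance on real homes, where activities sharing rooms and sensors
are far harder to separate.

## Problem sizes and numerical choices

Experiments run at the default 632-row scale (recovery: 20 simulated
cohorts; recognition: one cohort plus its null; importance tests: a
4-activity, 20-participant cohort). Tolerances: statistics oracle 1e-9,
moment identities 1e-12; PKFS vs its brute-force oracle and log
round-trips are exact equality. Degenerate inputs are pinned by tests:
constant features rescale to 0, constant vectors zero out the shape
statistics, empty row sets and sub-2 vectors are errors, and union sets
below 2 features refuse augmentation rather than emitting undefined
statistics.
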