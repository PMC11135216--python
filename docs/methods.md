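# Methods

## Problem and pipeline

`actithigh` classifies physical behavior (PB) from a single thigh-mounted
triaxial accelerometer sampled at a nominal 100 Hz in units of g. The device
convention is that the x axis points toward the floor in the standing
position, so quiet standing reads approximately (1, 0, 0) g and seated or
lying postures tip the gravity vector onto the y/z axes.

The pipeline is:

1. **Windowing.** The recording is segmented into 1 s windows advancing by
   0.5 s (50% overlap). A trailing partial window is dropped. Each window is
   assigned the ground-truth class covering the majority of its span; ties
   go to the earlier-starting annotation interval; windows with no coverage
   are dropped from training sets.
2. **Features.** Per window, seven time-domain statistics per axis — mean,
   sample SD, RMS, peak count, maximum, minimum, distinctive-point count —
   plus the three pairwise Pearson correlations: 24 features.
3. **Classifier.** A random forest over the 24 features, one prediction per
   window. The 0.5 s-spaced stream of window labels is the package's
   "second-by-second" output.
4. **Evaluation.** Confusion matrices (truth rows x predicted columns, fixed
   class order), per-class sensitivity / positive predictive value /
   F-measure, unweighted macro averages, stratified k-fold cross-validation,
   leave-one-subject-out evaluation, five-class merging, and per-class
   relative duration errors.

## Feature definitions and their parameters

Two of the per-axis statistics are thresholded operators whose exact
definitions are interpretation choices; both are parameters, not constants:

* **Peak count** is the number of local maxima with topographic prominence
  ≥ `peak_prominence_g` (default 0.1 g, via `scipy.signal.find_peaks`). A
  raw local-maximum count is dominated by sensor noise; prominence
  filtering makes the count track gait cycles rather than jitter.
* **Distinctive points** is the number of samples whose absolute first
  difference exceeds `distinct_threshold_g` (default 0.05 g) — a count of
  abrupt signal changes, monotone in movement intensity.

Other conventions: SD uses the n−1 (sample) denominator while RMS divides
by n; Pearson correlation is defined as 0 (not NaN) when either axis has
zero variance, which keeps static postures representable. Feature
extraction is deterministic bit-for-bit, and satisfies translation
(constant offset on one axis shifts mean/max/min only) and positive-scale
(k > 0 scales the moment statistics, leaves correlations) invariances,
which the test suite checks on random windows.

## Classifier configuration

"Default workbench" forest settings: 100 trees, unlimited depth, bootstrap
resampling, and `floor(log2(F) + 1)` candidate features per split (5 for
F = 24). Labels are encoded as integers in the canonical class order before
fitting, so equal-vote ties deterministically resolve to the earlier class
in that order. No class weighting or probability calibration is applied
even though training sets are typically imbalanced; the imbalance is
reported by `build_dataset` as a per-class window-count audit instead.

Model files are joblib containers carrying a magic string, schema version,
class order, feature-name schema, seed and tree parameters; loading
verifies all of these and prediction refuses feature matrices with the
wrong width.

## Cross-validation and the subject-leakage gap

`stratified_kfold` splits at the *window* level with a seeded shuffle, each
fold preserving class proportions to within one window. Because windows
overlap by 50% and many windows come from the same individual, neighboring
(nearly identical) windows routinely land in different folds; window-level
CV therefore estimates within-individual performance and is optimistic
relative to deployment on new people. `leave_one_subject_out` holds out
each subject's entire session and measures the deployment-like setting.
The package treats the gap between the two as a first-class quantity: on
simulated cohorts the subject-held-out macro F is consistently strictly
below the window-level CV macro F.

## Merging and duration errors

The five-class scheme maps sitting and lying to `sedentary`; walking, both
stair directions and transitioning to `walking`; keeps standing, cycling,
running; and excludes driving and wheelchair ambulation. Samples whose
ground truth is excluded are dropped before scoring. A retained sample that
an 11-class model predicts as an excluded class is mapped to an explicit
`other` pseudo-class column, which counts as an error against its true
class; the recommended alternative for merged reporting is retraining on
merged labels, which the CLI supports by merging annotations upstream.
Whether transitioning belongs in the coarse `walking` class is genuinely
arguable; the scheme object is a plain mapping and can be overridden.

The duration error for class c over a session is
|duration_alg − duration_gt| / duration_gt, with `duration_alg` counting
**all** windows predicted as c (not only correct ones) and each window
standing for dt = 0.5 s. Under the correct-only reading the error could
never exceed 100%, yet heavily over-predicted classes plainly can exceed
it; the all-predictions reading is the one consistent with reported
over-100% errors in practice, so it is the implemented arithmetic.

Macro averages are unweighted over the classes present in the matrix. Any
0/0 metric (a class absent from truth or predictions) is reported as 0 with
a warning, never NaN. Reports round percentages to one decimal.

## Reference confusion matrices

Four published validation-scale confusion matrices ship as fixed integer
tables (`actithigh/data/*.csv`): an 11-class stratified 10-fold
cross-validation, the same model on subject-held-out sessions, the merged
five-class evaluation, and a threshold-based comparison algorithm on the
same sessions. They exercise the metric arithmetic end to end against
realistic imbalance; recomputing their per-class and macro F-measures
reproduces the originally reported percentages to within 0.1 pp, with one
exception: the 11-class cross-validation table yields a macro F of 92.9%,
0.14 pp above its originally reported headline of 92.8% — the published
headline is internally inconsistent with its own table, and this package
reports what the table arithmetic gives.

## The simulator

The generator emulates exactly the structure the 24 features can resolve:

* **Gravity projection.** Each class has a unit orientation vector;
  standing ~(1,0,0), seated postures ~(0.20,0.10,0.97), lying tips gravity
  onto y. Transitioning alternates between the seated and standing
  orientations with smooth cosine ramps of 1–3 s separated by 0.5–2 s
  dwells.
* **Periodic components** for the gaits (frequency Hz / dominant-axis
  amplitude g): walking 1.8 / 0.35 with a second harmonic, running
  2.8 / 0.95, stair ascent 1.6 / 0.30 and descent 1.7 / 0.38 with
  different x:z amplitude ratios and phases, cycling a smooth 1.4 / 0.28
  with low noise. Frequencies jitter by a few percent per bout with a
  random phase.
* **The hard seated group.** Driving is the sitting orientation plus
  broadband vibration (noise SD 0.028 g vs 0.012 g for sitting — the mean
  orientation difference is below the driving noise floor); wheelchair
  ambulation is the sitting orientation plus intermittent 1.1 Hz push
  bursts (0.16 g, 1–2 s on, 1–3 s off). These three are deliberately the
  least separable group, while running is the most separable.
* **Noise** is Gaussian and white; there is no 1/f component, no
  biomechanically realistic gait waveform, no disease-specific movement
  pattern. Sessions concatenate bouts with a 0.5 s linear cross-fade;
  annotation intervals match the script exactly. Optional triple-tap
  markers (three 3 g spikes 0.15 s apart) are injected into quiet padding
  at the session start and end.
* **Subject random effects** (cohorts): one device-placement rotation of up
  to ±10° shared across a subject's classes, an amplitude factor
  U(0.8, 1.25), a cadence factor U(0.9, 1.1) and a noise factor
  U(0.8, 1.25). These create genuine between-subject distribution shift so
  leave-one-subject-out evaluation is a harder problem than window-level
  CV, as it is with real cohorts.

All constants were chosen once for physiological plausibility (typical
walking cadence ~1.8 Hz, running ~2.8 Hz, seated thigh near-horizontal);
they are not fit to any dataset. Every level (bout, session, cohort) is
deterministic per seed.

**What passing simulator-based tests does and does not show.** The
simulator validates the pipeline's bookkeeping (windowing, labeling,
splitting, metric arithmetic) and its qualitative behavior (class
separability ordering, CV-vs-held-out gap). It does not validate
classification accuracy on real human movement: real gait has richer
harmonics, autocorrelated noise, behavioral heterogeneity and annotation
error, so absolute F-measures on simulated cohorts are optimistic.

## Problem sizes used in checks

Simulated acceptance checks use cohorts of 6 subjects with one 50 s bout
per class per subject (5 minutes of signal per class across the cohort,
~6.6k labeled windows), repeated over 10 seeds for the CV-vs-held-out
comparison; tap-marker checks use 10 sessions of 8 s bouts of all 11
classes. These sizes give stable statistics (macro F standard deviation
across seeds ≈ 0.002 for CV) while keeping the full suite quick to run.

## Known limitations

* Binary vendor formats (e.g. .cwa) are not parsed; recordings enter as
  CSV exports. Clock-drift correction and multi-sensor fusion are out of
  scope.
* Tap-marker detection parameters (2 g threshold, 0.5 s max gap, 0.1 s
  refractory) are configurable defaults, not calibrated values.
* Window-level CV retains overlapping windows across folds by design (it
  reproduces the standard, optimistic protocol); use
  `leave_one_subject_out` for deployment-like estimates.
* Frequency-domain features and automatic feature selection are
  deliberately absent; the 24-feature set is fixed.
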