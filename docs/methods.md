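# Methods

## Problem and approach

Stroke survivors practicing upper-limb tasks at home often substitute
compensatory movement patterns (trunk flexion, shoulder hike/abduction,
altered grips, nonparetic-hand assistance) for the impaired movement
components; unsupervised practice of poor quality works against recovery.
This package classifies the movement quality (correct vs incorrect) of
each home task repetition from a single wrist-worn 9-axis IMU
(accelerometer, gyroscope, magnetometer at a nominal 100 Hz), using the
participant's own therapist-labeled lab trials as reference data.

The classifier is deliberately simple and fully participant-specific:

1. **Gravity separation.** An error-state Kalman filter fuses
   accelerometer and gyroscope (six-axis only — the magnetometer is never
   fused, since yaw is irrelevant to gravity) to split the accelerometer
   signal into a gravity vector and linear acceleration, both in the
   sensor frame.
2. **Windowed multivariate DTW.** Two trials are aligned by dynamic time
   warping over the Euclidean local cost across the selected channels,
   restricted to a Sakoe–Chiba band |i − j| ≤ w.
3. **Projected distance.** Reference samples matched to each test index
   are averaged and the mean per-test-sample Euclidean distance is
   reported, so distances are comparable across trial durations.
4. **Method selection.** A grid over channel combinations
   ({lin_acc, grav, gyro}, optionally mag), per-axis normalization
   on/off, and window sizes {50, 100, 200, 300, 400} samples (0.5–4 s at
   100 Hz) is scored on the lab session; see below.
5. **1-NN labeling.** Each home trial takes the quality label of the lab
   trial with minimum projected distance.

## Method selection

For every unordered pair of lab movement types with opposite quality
labels, the within-type projected distances (both types pooled,
self-pairs excluded; distances are directed, both directions included)
are compared against the between-type distances (both directions) with a
one-sided Welch t-test (alternative: within < between). The maximum p
over pairs — and over tasks, when the session spans several — summarizes
a method's discernability. Methods with p_max < α (default 0.05) form
the candidate set (argmin p_max if none pass); leave-one-trial-out 1-NN
accuracy on the lab trials breaks ties; remaining ties prefer
lin_acc+grav+gyro with normalization, then the longer window, then the
canonical channel order. Welch rather than a pooled-variance test
because the two distance clusters have no reason to share a variance.
No multiple-testing correction is applied across the grid: the p-values
rank methods, they are not inferential claims.

Magnetometer-containing channel sets sit behind a flag (off by default):
the magnetometer tracks heading relative to the earth field, which
changes between lab and home, making it an unreliable movement cue.

## Orientation filter

The filter is a multiplicative/error-state Kalman filter: the nominal
state is the sensor-to-world unit quaternion, propagated by gyroscope
integration; the 3-dof attitude-error covariance is corrected by the
normalized accelerometer direction, whose measurement variance is
inflated by `dynamic_gain · (|f|/g − 1)²` so corrections switch off
during vigorous movement. Tilt is initialized from the first
accelerometer sample (yaw is unobservable and irrelevant). Defaults:
gyro noise 0.02 rad/s, accelerometer direction noise 0.05, dynamic gain
2.0. The gravity output has fixed magnitude g = 9.80665 m/s² by
construction; linear acceleration is defined as the raw accelerometer
minus gravity, so the two reconstruct the input exactly. The first
0.25 s are not trimmed: trials are whole-movement segments and trimming
would change lengths; a configurable trim exists for callers that want
it.

Verified behavior (tested): static trials at random orientations recover
the gravity direction to < 1° after 1 s; ideal rotating trials track the
true gravity direction to < 2° RMS.

## Normalization

Per-axis scales are the sample (n−1) standard deviation over the
concatenation of the participant's lab trials for the task; the same
lab-derived scales are applied to home trials, keeping home
classification causal with respect to the reference data (pooling home
data into the scales would leak). Constant channels fall back to scale 1
with a warning. Normalization divides only — no centering.

## DTW numerics

Local cost: Euclidean norm across channels (dependent multivariate DTW),
pairing naturally with per-axis normalization. DP tie-breaks in the
backtrack are diagonal-first, then test-advancing, so paths and
distances are bit-reproducible. A window smaller than the length
difference of a pair raises an explicit infeasibility error; the
selection layer marks such methods infeasible rather than scoring them,
and classification flags trials unclassifiable (reported separately)
rather than silently dropping them. Projection semantics — averaging the
matched reference samples per test index and averaging distances over
the test length — is one of several defensible readings of
length-consistent DTW distance; it is this package's documented choice.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not any
individual's recordings. Trials are rigid-body movements: Euler-angle
trajectories (minimum-jerk smoothstep ramps plus mid-movement bumps) and
a minimum-jerk translation with a vertical peak, differentiated
analytically so accelerometer (specific force R^T(a + g)), gyroscope
(true body rates) and magnetometer (rotated earth field, 50 µT at 60°
inclination) are mutually consistent by construction. Home sessions
apply a 60° yaw offset to the earth field to emulate the lab-vs-home
heading change.

Default conditions mirror the targeted protocol: 4 tasks; per task a
correct type (6 lab trials) and two compensatory types (3 lab trials
each); 75 home trials per task with 70% performed correctly. Sensor
noise defaults — accelerometer 0.05 m/s², gyroscope 0.01 rad/s, gyro
bias random walk 1e-3 rad/s·√s, magnetometer 0.5 µT — are typical of
consumer MEMS wrist loggers; inter-trial variability uses an amplitude
multiplier sd of 0.1, duration 3.0 ± 0.3 s, and a smooth monotone time
warp (strength sd 0.08). Compensatory signatures: trunk/shoulder
involvement = added pitch bump + roll offset + raised, shortened path;
compensatory grip = altered final wrist-extension angle + 40% larger
transport amplitude; unable-to-complete = truncation at 40–70% of the
movement; nonparetic assist = wrist amplitude scaled to 15%. All
magnitudes scale with a single `effect_scale` dial used by the
separability studies. Seeding: per-trial generators derive from
`SeedSequence([root, task, phase, index])`, so any subset of trials
regenerates identically.

What the generator does *not* emulate: real sensor artifacts (clipping,
dropped samples, temperature drift), biomechanical coupling between
joints, skin motion, within-session fatigue, or the heterogeneity of real
impairment. Passing the end-to-end studies therefore demonstrates that
the pipeline's machinery is correct and that the selection procedure
recovers the informative channels under realistic noise — not that the
specific accuracy figures transfer to clinical recordings.

## Validation studies and problem sizes

The studies in `tests/test_acceptance.py` and `scripts/acceptance.py`
run at sizes chosen to keep a laptop run comfortable while preserving
the study conditions: the end-to-end feasibility study uses 10 seeds of
the full default configuration (the acceptance script uses 5, pooling
~1500 home trials); the DTW oracle study uses 500 random short pairs
against an exhaustive-path recursion; null calibration uses 1000
simulated within/between draws. The acceleration-only ablation runs on
the gyroscope-differentiated scenario, where the information loss is
designed to be total — the expected direction (all-channels wins) is the
point, the gap's size is scenario-specific.

## Known limitations

- The projected-distance convention (mean-of-matched, mean-over-test) is
  a documented interpretation; other conventions would change absolute
  distances but rarely the 1-NN ordering.
- LOTO accuracy is scored at the quality level (correct/incorrect), the
  label the classifier ultimately emits; type-level accuracy is not used
  for selection.
- Home trials whose movement type never appears in the lab reference set
  are scored normally and surface in the per-type sensitivity table;
  nothing special is done for them, matching the reference-based design.
- The pipeline consumes pre-segmented trials; segmentation of continuous
  home streams is out of scope.
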