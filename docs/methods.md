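# Methods

`motionid` studies per-user authentication of children sharing a tablet from
inertial sensor streams: given 100 Hz accelerometer (gravity units) and
gyroscope (rad/s) recordings collected while a child lays for 10 minutes and
then sits for 5 minutes using the device, can a one-vs-rest model recognize a
target child's 1-second windows — and how do the *length*, *time proximity*
and *position composition* of the training data affect that?  The real child
cohort is not publicly available, so the package ships a seeded synthetic
generator that emulates the statistical structure the analysis depends on;
every experiment here runs end-to-end on that generator.

## The synthetic cohort generator

Each synthetic user carries a stable **motion signature**:

| parameter | unit | population mean | per-user offset SD |
|---|---|---|---|
| base orientation, laying (yaw, pitch, roll) | rad | (0, 0, 0) | 0.20 per axis |
| base orientation, sitting | rad | (0, 0.6, 0.1) | 0.20 per axis |
| tremor amplitude (per accel axis) | g | 0.02 | 0.008 |
| tremor frequency (per axis) | Hz | 2.5 | 1.2, clipped to [0.5, 8] |
| gyroscope noise scale (per axis) | rad/s | 0.02 | 0.008 |
| attitude drift rate | rad/min | 0.03 | 0.01 |

A cohort-level `separation` multiplier scales every per-user offset;
`separation = 0` collapses all users onto the population mean.  The sampled
stream is

* attitude(t) = base orientation for the current position (with a 2-second
  smooth ramp at the laying-to-sitting boundary) + an Ornstein–Uhlenbeck
  random walk (mean-reversion time constant 300 s; innovation scaled so the
  free walk accumulates `drift_rate` radians of standard deviation per
  minute).  OU rather than Brownian drift keeps excursions bounded and the
  stream physically plausible over 15 minutes.
* accelerometer(t) = gravity expressed in the device frame (intrinsic
  yaw–pitch–roll rotation; a static face-up device reads (0, 0, −1)) + a
  per-axis sinusoidal tremor + white noise with standard deviation 0.3 × the
  tremor amplitude (tying the noise floor to the tremor scale keeps the
  zero-tremor stream exactly noise-free, a useful degenerate case).
* gyroscope(t) = the attitude derivative (roll, pitch, yaw rates on X, Y, Z)
  + white noise at the signature's gyro noise scale.

All randomness fans out from explicit integer seeds via `SeedSequence`, so
cohorts, streams and downstream results are bit-reproducible.

**What the generator does and does not emulate.**  It reproduces the three
structural properties the experiments measure: users are separable within a
position (signatures differ), positions impose different orientation regimes
(so cross-position transfer collapses), and windows decorrelate with time
distance (drift).  It does *not* model touch interactions, app content, body
adjustments, re-grips, or any non-stationarity beyond smooth drift, and its
noise is Gaussian.  Passing tests therefore demonstrate that the pipeline
detects these effects when they exist — not that a real cohort of children
would yield any particular F1.

**Calibration of the separation default.**  The inter-child separation of
real motion signatures is unknown, so the default (`separation = 2.0`) was
calibrated empirically against the qualitative regime the analysis is
designed to exhibit: same-position, adjacent-time authentication near
ceiling and *flat* as earlier-session data is added; a forward sweep rising
from ≈ 0 as training approaches the test block; and a collapse under position
cross-over.  At weaker separations the grid search occasionally prefers
k = 100/200 neighbors, whose votes dilute once the nine laying minutes enter
training (there exist only 180 same-position target windows), which makes the
trimmed sweep drift downward instead of staying flat — a genuine k-NN
behaviour, but not the regime under study.

## Windowing, features, normalization

Streams are cut into non-overlapping 1-second windows anchored at the first
timestamp; a trailing partial second is dropped; a window straddling the
position boundary takes the majority label (exact ties go to the
earlier-in-time label).  Rows duplicated by logging-layer buffering are
deduplicated on the since-reboot timestamp, keeping the first occurrence.

Each window yields 8 statistics × 7 signals = **56 features**: mean, max,
min, RMS, variance, SD, skewness and kurtosis of yaw, pitch, roll, the three
accelerometer axes, and the accelerometer vector magnitude.  Conventions,
chosen once and shared by training and testing:

* pitch = atan2(−ax, √(ay² + az²)), roll = atan2(ay, −az) — accelerometer
  tilt under the face-up rest pose; yaw = cumulative trapezoidal integral of
  the gyroscope Z (yaw-rate) channel, reset to zero at each window start.
  No magnetometer is logged, so absolute heading is unobservable; only
  within-window yaw motion is informative.  This derivation is the least
  constrained step of the pipeline (attitude can equally come from a
  platform's fused stream), so it is documented prominently here.
* moments are population moments (divide by n); skewness m₃/m₂^1.5 and
  *excess* kurtosis m₄/m₂² − 3, both defined as 0 for a constant signal.
* vector magnitude is computed on the accelerometer axes only.

Min–max normalization is fit on the **training split only** and applied to
test data without clipping, so out-of-range test values exceed [0, 1].
Fitting scope is a leakage-free design choice; a global fit is a one-line
sensitivity variant.

## Models

Per-user (one-vs-rest) classifiers score each test window in [0, 1]; the
decision threshold is fixed at 0.5 (ties positive).  Classical models are
tuned by exhaustive grid search with stratified threefold cross-validation
on the training rows, selecting by positive-class F1 with ties broken by
first-in-grid order, then refit on all training rows:

* **k-NN**: k ∈ {5, 10, 100, 200} (values exceeding the smallest CV training
  fold are skipped with a warning).  The search shares one neighbor query
  per fold across all k, which is algebraically identical to per-setting
  search and verified against scikit-learn's `GridSearchCV` in the tests.
* **Random forest**: max depth ∈ {10, 50, 100}, 100 trees.
* **Neural network**: one hidden layer of 100 rectified units, Adam, L2
  strength α ∈ {10⁻¹ … 10⁻⁵}.  Only α is grid-searched; the topology is a
  fixed simple choice.

The **dual-stream transformer** consumes raw per-sample window sequences
(yaw, pitch, roll, accelerometer X/Y/Z; 100 × 6).  Two streams — one over
the raw sequence, one over per-channel rFFT magnitude spectra (phase
discarded) — each apply a 1-D convolutional embedding (kernel 5 → 32
dimensions), sinusoidal positional encoding, and a self-attention encoder
layer (2 heads, post-norm residual blocks, 2× feed-forward width).  The two
mean-pooled embeddings are concatenated into an MLP with a single sigmoid
output; training minimizes binary cross-entropy with Adam (default 15
epochs, batch 128, lr 10⁻³ — sized so one per-user model trains on about a
thousand windows in under a minute on one CPU core).  It is implemented in NumPy float64 on a small
reverse-mode autodiff engine written for this package (gradients are
finite-difference-checked in the tests); runs are single-threaded and
bit-deterministic given the config seed.  Per-channel standardization
statistics are computed on the training sequences and stored with the model.
Layer counts and epochs are implementation choices; they are recorded in the
model's provenance metadata.

Class imbalance (1 target vs 31 negatives) is left unweighted by default; a
class-weight flag on the classical estimators is a sensitivity option.

## Experiment families

Four decoys per cohort are chosen once per seed and held constant across all
analyses; they never enter any training matrix but always appear in test
sets (unseen negatives).  Every run asserts decoy purity and train/test
window disjointness.

* **Decoy protocol**: per target, train on one random laying minute + one
  random sitting minute from each of the 32 non-decoy users; test on the
  last 3 sitting minutes of the target and the 4 decoys.  The target's
  random sitting minute is drawn from the sitting minutes outside the test
  block so the same user's train and test never overlap in time (the
  protocol description leaves this collision unaddressed; excluding it is
  the only leakage-free reading).
* **Length/proximity sweeps**: the training timeline is 12 minutes — the
  last 9 laying plus the first 3 sitting minutes (which laying minute to
  drop is unspecified upstream; the first, as a warm-up minute, by default
  and configurable).  Test is always the last 2 sitting minutes.  *Forward*
  growth selects timeline minutes 1..m (gap-to-test 12 − m); *backward*
  trimming selects the last m minutes (gap 0).  m = 12 coincides in both.
* **Position cross-over**: train {2 min laying | 2 min sitting | 1 + 1
  mixed} × test {last 2 laying | last 2 sitting} minutes, with a sliding
  offset enumerating every consecutive same-position block not overlapping
  the test block (7 laying candidates, 2 sitting candidates; mixed pairs
  enumerate laying × sitting minutes).  For cross-position training the
  "before the test block" constraint is vacuous (all sitting follows all
  laying), so any non-overlapping block is valid.
* RQ-style random minutes are protocol-minute-aligned (not arbitrary 60-s
  spans): direct-observation labels in the emulated study are recorded at
  whole activity boundaries, and minute alignment keeps selections
  enumerable and reproducible.

## Metrics and reporting

Precision, recall, F1 and accuracy per target, with precision/recall/F1
defined as 0 when their denominators vanish (matching the F1 = 0 outcomes in
degenerate conditions).  Metrics are summarized across targets by median and
25th/75th percentiles (linear interpolation between order statistics), since
the metrics are bounded at 1 and skewed across targets.  Reports are
deterministic CSV tables, line/box plots, and a JSON manifest linking every
file to the specs and seeds that produced it.

## Problem sizes in the test suite

The acceptance tests run the full pipeline at the study's cohort scale
(36 users, 10 + 5 min at 100 Hz, 4 decoys, full grids) but pool sweep
medians over 3 targets × 3 cohort seeds, and run the transformer's position
contrast in a reduced-scale mode (8 training users + 4 decoys, 4 targets,
16-dimensional embedding, 12 epochs) so the whole suite completes in minutes
on one CPU.  These sizes are package choices for a desk-scale check; the
library itself runs all 32 targets (see the command-line interface's
`--n-targets`).

## Known limitations

* Synthetic-only validation: no claim is made about real-cohort F1 values.
* Single-session modeling; no cross-day or free-living generalization.
* The attitude derivation is one of several defensible conventions; feature
  values are convention-dependent even though downstream conclusions are not.
* No EER/ROC verification mode; the classifier is a fixed-threshold decision
  pipeline by design.
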