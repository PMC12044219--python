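# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, what the synthetic generator does and does not emulate,
and where the design was genuinely open.

## The lateral gait cycle and its labels

A lateral step is divided into four phases by foot-ground contact: narrow
double support (NDS), guided foot swing (GFS; the leading leg is airborne),
wide double support (WDS), and follow leg swing (FLS; the trailing leg is
airborne), cycling NDS→GFS→WDS→FLS. Contact is measured by two pressure
sensors per foot (first metatarsal, heel); a foot is in the touch state
when **either** sensor exceeds its threshold — the OR rule is what "touch
state" means with two sensors on one foot. NDS and WDS share the
double-support contact state and are separated by cycle order, implemented
as a two-state memory of the last swing phase, initialized to "after FLS"
so a session standing at rest begins in NDS.

The contact threshold is `baseline + k·(max − baseline)` per channel with
baseline and max taken as the 5th and 95th percentiles (robust to spikes)
and k = 0.2 by default. The published account of the recording system
defers the exact threshold formula to earlier work without restating it;
this k-fraction rule is a documented stand-in, configurable end to end.
Contact runs shorter than 20 ms are treated as threshold chatter and
absorbed (debouncing); simultaneous double-off — impossible in lateral
walking — is imputed from the previous sample by default, or raised as an
error.

Within-phase percentage maps each maximal run of one phase linearly to
[0, 100]; a per-cycle variant is available behind a flag.

## Synthetic sessions

The generator is the package's study-condition definition, not a fixture.
One seeded configuration produces a deterministic session:

- **Schedule**: `n_steps` cycles of 1.46 s split by phase fractions
  (0.28, 0.22, 0.28, 0.22) — double supports slightly longer than swings —
  with optional per-phase LogNormal(0, σ = 0.05) duration jitter.
- **EMG** (6 channels, 1000 Hz): zero-mean Gaussian noise band-limited to
  20–400 Hz, amplitude-modulated by a per-muscle phase envelope plus a
  baseline noise floor (0.05 units). Leading-leg muscles burst during GFS,
  following-leg muscles during FLS (peak amplitudes 0.55/0.45/0.50 units
  for the three muscles of a leg). Inside the burst phase the envelope is
  a raised-cosine bump centred early / mid / late in the phase per muscle,
  as in real phasic EMG where synergists peak at different sub-phases;
  this staggering is what makes within-phase progress decodable from
  amplitude features, and hence continuous angle regression possible at
  all. Tonic activity differs between the two double supports (0.025 in
  NDS vs 0.060 in WDS) reflecting the higher abductor demand of a wide
  stance; without a postural difference the two statically similar phases
  would be physically indistinguishable from EMG. The envelope is smoothed
  with a 25 ms Hann kernel so no discontinuity a muscle could not produce
  remains.
- **Hip angles** (2 channels, 200 Hz): the leading (right) hip rises along
  a half-cosine from 0 to `angle_amplitude` (default 25°) during GFS,
  holds through WDS, and returns during FLS; the following (left) hip is
  the half-cycle mirror. Both are constant during double support. With
  these smooth swing ramps the phase identity explains
  2s/(2s+f) ≈ 72% of angle variance (s, f = stance and swing fractions);
  the remainder lives in within-phase progress, which is exactly what the
  cascaded regressor must extract from the feature vector.
- **Pressure** (4 channels, 200 Hz): high (1.0) during contact, baseline
  (0.02) when the foot is airborne, with transitions aligned to the
  schedule sample grid. Transitions are sample-sharp by default so that
  contact-based relabeling reproduces the generating schedule exactly —
  the round-trip is the labeling module's ground-truth test. Optional
  additive noise models sensor jitter below the threshold margin.

What the generator does **not** emulate: motor-unit firing statistics,
inter-muscle crosstalk, electrode lift artifacts, fatigue drift,
inter-subject variability, or pathological gait. Tests passing on this
data demonstrate that the pipeline recovers structure it is designed for;
they do not certify performance on real recordings, whose separability is
unknown and certainly lower.

## Preprocessing

EMG: 4th-order Butterworth band-pass 20–400 Hz plus a 2nd-order IIR notch
at 50 Hz (Q = 30), both applied forward–backward (zero phase) since the
pipeline operates on buffered windows; a causal single-pass mode exists
for streaming. Filter order and notch bandwidth are documented defaults —
the published pipeline states the passband and notch frequency only.
Angles arrive Kalman-smoothed inside the inertial sensor and receive no
further filtering. The 200 Hz streams are linearly interpolated onto the
1000 Hz EMG clock: pressure is quasi-binary and angles are smooth, so
higher-order interpolation adds nothing; the induced phase-boundary shift
is bounded by one kinematic sample (5 ms). All streams share t = 0 (the
acquisition hardware synchronizes them); per-stream offsets are a
parameter for misaligned files.

## Features

Each 250 ms window (increment 3 ms) of each channel yields, in fixed
order: max, variance, mean absolute value, mean, min, RMS, zero-crossing
count, SD. Two interpretation notes: the feature sometimes listed as
"mean absolute error" has no reference signal to be an error against and
is implemented as the mean absolute value (MAV), the standard EMG
amplitude feature; variance and SD use the sample (n−1) denominator,
configurable. Zero crossings count strict sign changes between
consecutive samples, with an optional amplitude-hysteresis band (default
0) to suppress noise crossings. The window's phase label and angles are
taken at its final sample — the real-time system predicts the present
from the trailing window — with majority vote as an alternative policy.
Features are z-scored with training-set statistics stored in the model.

## The two networks

**Elder Brother** (phase classifier): input 48×1×1 → conv 3×3/32, ReLU →
conv 3×3/64, ReLU → squeeze-excitation gate → 2×1 max-pool → LSTM(48) →
dense 64, ReLU → dense 16, ReLU → dense 4, softmax. Kernels are full 3×3
windows (parameter counts 320 and 18,496) applied to unit-width maps with
zero-padded width, so only the centre kernel column sees data. The
attention weights are computed from the first conv's maps (global average
pool → dense 32→8, ReLU → dense 8→64, sigmoid) and applied to the second
conv's maps, following the architecture's narrative description; an
alternative placement after the LSTM is available behind a config flag.
The pooled 22×1×64 map enters the LSTM as a 22-step sequence of 64-dim
vectors (a literal 1408-dim single step would be inconsistent with any
plausible recurrent parameter count); the final hidden state feeds the
dense head. Dense-head parameter counts: 3,136 / 1,040 / 68.

**Younger Brother** (regressor): 49 → 20 → 12 → 6 → 1, ReLU on hidden
layers, linear output (parameter counts 1,000 / 252 / 78 / 7). The 49th
input is the elder's hard phase decision encoded as code/3 ∈ [0, 1],
matching the printed input width; a soft-probability 52-input variant is
behind a flag. One head per target (left angle, right angle, phase
percentage), trained independently; by default the younger trains on the
elder's *predicted* phases so training matches deployment
(teacher-forcing on ground-truth labels is a flag). Regression targets are
z-scored for training and mapped back to physical units at prediction, so
convergence within a fixed epoch budget does not depend on whether the
target is an angle in degrees or a percentage on the 0–100 scale; the
statistics are stored with the head.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the standard defaults),
initial lr 0.01 dropping ×0.1 every 700 epochs, mini-batches of 128
reshuffled every epoch, 850 epochs at full scale. The learning-rate
period is read in epochs, consistent with the 850-epoch recipe. Gradient
clipping at global norm 5 guards the lr = 0.01 LSTM path; cross-entropy
clamps probabilities at 1e-12 instead of raising. The whole core is plain
float64 numpy with manual backpropagation; every layer's gradient is
verified against central finite differences in the test suite.

### When does the cascade help?

The elder's phase decision is a deterministic function of the same
48-feature vector the younger sees, so it adds no *information* — its
value is as a capacity shortcut: a deep classifier hands the tiny 20-12-6
regressor a computed quantity it could not reliably compute itself. The
consequence, measured on synthetic sessions: when the target is smoothly
decodable from the features (the staggered-burst angle trajectories;
held-out R² ≈ 0.995 either way), the phase input is redundant and a
mispredicted hard code can even interfere; when the target depends on the
phase beyond the regressor's own capacity (a phase-determined level plus
noise), the cascade cuts held-out MSE several-fold, for every seed. On
such a discrete-level target a mispredicted phase code costs the full
level jump, so classifier boundary noise obscures the architectural
comparison; the cascade experiments therefore teacher-force the phase
channel (ground truth) and use the phase-determined target — the regime
the architecture was designed for, measured cleanly.

## Evaluation conventions

Per-phase metrics are one-vs-rest; "mean" rows are macro averages over
the four phases. AUC uses the rank (Mann–Whitney) statistic with tie
averaging, identical to trapezoidal integration of the ROC curve.
Undefined ratios (zero denominators) report 0 with a warning rather than
raising, so parameter sweeps never abort. Paired t-tests delegate to the
classical two-sided statistic with df = n−1. Latency in the streaming
harness is measured and logged, never asserted: it is hardware-dependent.

## Train/test protocol and problem sizes

The package defaults to a chronological 70/30 holdout for the end-to-end
pipeline; shuffled ("scrambled") splits and k-fold cross-validation over
pooled windows are config options. The test suite's recovery experiments
run on one seeded 10-step session (~14.6 s, ~4,800 windows at
250 ms / 3 ms) with 100-epoch training — deep enough for the loss plateau
on separable synthetic features while keeping a full suite run in minutes.
The session length matters more than the window count: overlapping windows
are highly correlated, so held-out generalization is governed by the
number of independent gait cycles, and shorter sessions show visible
seed-to-seed swing in regression R². The
comparison classifiers are evaluated under the scrambled 7:3 protocol
with correspondingly reduced epochs (60–100); with 3 ms increments
adjacent windows overlap by 98.8%, so the scrambled protocol is easier
than the chronological one — both are reported as what they are.

## Known limitations

- Synthetic separability is by construction; real NDS/WDS discrimination
  rests on postural EMG differences whose size is an empirical question.
- Within-phase *percentage* regression has a structural ceiling on this
  synthetic data (R² ≈ 0.45): the generator's double-support EMG is
  constant tonic, so progress within a stance phase has no EMG correlate.
  Real recordings carry postural drift that encodes it; the harness
  reproduces the experiment's structure, not its attainable accuracy.
- The angle model is deterministic given the schedule; no stride-to-stride
  amplitude variability or soft-tissue artifact is simulated.
- The LSTM parameter count of the reference architecture table (2,400)
  is inconsistent with every standard LSTM formula for the stated shapes;
  hidden size 48 is implemented and the table's figure is not enforced.
  Likewise the first younger hidden layer's printed 980 parameters
  conflicts with a biased 49→20 layer (1,000).
- Response-time targets are platform statements, not package contracts.
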