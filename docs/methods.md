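# Methods

This note records the modeling and numerical choices behind gaitmark:
what is computed, which parameters matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Pipeline model

A recording is a uniformly sampled stream of 10 IMU channels plus one
footplate pressure channel. The default sample period is 10 ms (100 Hz),
chosen so that the 300 ms classification window is exactly 30 frames and
the 10 ms window step is exactly one frame; both are configurable.

Processing order:

1. **Limiting filter** (Euler channels only). If a sample deviates from
   the previous *output* by more than a threshold it is treated as a
   random pulse and replaced by that previous output (hold-last-valid).
   This preserves length and causality and is idempotent. The threshold
   has no principled universal default — it depends on the angle units
   and sampling rate — so it is configuration; for the synthetic data's
   scales (degree-like Euler channels, 100 Hz) 40 units separates smooth
   motion (per-step changes < ~12) from injected pulses (±100).
2. **Gait events.** FC where pressure rises through `on`, FO where it
   falls through `off`, with `on ≥ off` (hysteresis) and a 100 ms
   debounce that drops crossing pairs closer than the minimum phase
   duration. Defaults: on = 20 % and off = 10 % of the recording's
   maximum pressure. Pressure units therefore never matter.
3. **Cycles.** One cycle per consecutive FC pair containing exactly one
   interior FO; anything else (sensor stuck high/low, partial trailing
   cycle) is dropped and logged. Stance = frames before FO, swing =
   after.
4. **Windows.** Half-open `[start, start + W)` ranges, 0-based. A window
   takes the label and gait phase of the cycle containing its **final**
   frame, mimicking a causal online recognizer deciding "now". Windows
   ending outside any labeled cycle are unlabeled. A consequence worth
   knowing: windows whose final frame just crossed a pattern boundary
   contain mostly the *previous* pattern, so even a perfect classifier
   on noise-free data shows a small (~1 %) error floor at transitions;
   the causal majority vote adds a few frames of switching delay.

## DTW matching and normalization

Local cost: squared Euclidean distance over the 10 channels. Cumulative
cost: the standard three-predecessor recursion, with border cells
accumulating along their only predecessor (the boundary convention is
not uniquely fixed by the recursion alone; this is the standard choice
and is what the brute-force oracle in the tests assumes too). No warping
window or slope constraint. Backtracking breaks ties diagonal-first,
then vertical, for determinism.

Thresholding uses the **normalized** cost (cumulative ÷ path length):
cycle lengths vary, so raw cumulative costs are not comparable across
cycles. Query cycles are z-scored per channel with the template
library's statistics (computed from the template-building set only —
test data reuses training statistics, so there is no leakage). Note that
normalized costs still scale with sensor noise: with z-scored channels
the matched-template cost floor is roughly the per-step noise energy, so
"good" k values are data-dependent (see below).

## Templates

Each cycle is resampled with per-channel cubic splines onto a fixed
phase grid — stance to 60 points, swing to 40 points (N = 100; the 60/40
split follows the standard ~60 % stance share of a gait cycle) — which
aligns the FO event at the same row of every normalized cycle. The
template is the pointwise mean of the z-scored, phase-normalized cycles;
averaging z-scored (rather than raw) cycles keeps the template on the
same scale the DTW comparison uses. Cubic interpolation needs at least
4 samples per phase; shorter phases raise an error naming the cycle.

## Threshold k: two selection modes

* **Labeled same-day tuning** (`tune_k`): templates from the morning,
  auto-label the afternoon, sweep a grid of k and report SR/DR at each;
  k* is the smallest value maximizing SR subject to DR ≥ 0.9. SR is
  computed over *selected* cycles (that is what the threshold trades
  against DR). The default grid is self-calibrated — 40 values spanning
  the observed best-cost range — because absolute cost scales move with
  the noise level. No classifier is involved: SR and DR are pure
  functions of the DTW labels.
* **Unlabeled-day selection** (used inside the cross-day experiments
  when k is not supplied): k is set to the cost quantile achieving a
  target DR (0.9) on the very day being labeled. Day-to-day wear shifts
  inflate all template costs roughly uniformly, so an absolute k tuned
  on another day under-selects badly, while rank-based selection keeps
  the most template-like 90 % of cycles regardless of drift — and the
  *argmin over templates* is itself robust to a common cost offset.

Postprocessing: both members of every adjacent disagreeing cycle pair
lose their swing-phase windows (transitions happen in swing); stance
windows are kept. Suppression only ever removes data.

## Classifiers

Stance and swing get separate models; prediction routes each window by
its phase.

* **QDA** on the flattened window behind a PCA front-end (40 components,
  capped below the smallest class count): quadratic discriminants need
  more samples per class than features, which 300 raw dimensions rarely
  allow. Covariance regularization 0.1.
* **SVM**: C-SVC, polynomial kernel (degree 3, C = 1, coef0 = 1),
  one-vs-one — 10 binary classifiers for 5 classes.
* **CNN** (NumPy, authored here): C1 = 5 kernels of 5×2 (valid, no
  padding) → S1 = 2×1 average pool → C2 = 8 kernels of 4×2 applied to
  each incoming map separately (5 × 8 = 40 maps) → S2 = 2×1 average
  pool → softmax. On a 30×10 window: 26×9×5 → 13×9×5 → 10×8×40 →
  5×8×40 → flatten(1600) → S. The constructor audits every shape and
  fails loudly on any configuration that breaks the tiling. tanh
  activations; pooling is plain block averaging.
* **LSTM** (NumPy): single layer, hidden size 64, softmax on the last
  hidden state, full backpropagation through time (forget-gate bias 1).

The networks train with Adam (lr 3e-3, batch 64, ≤ 40 epochs), a 10 %
validation split and early stopping (patience 8), restoring the best
parameters. Backpropagation is verified against central differences in
the test suite. All randomness flows from the classifier spec's seed, so
identical spec + seed + data reproduce identical models. None of the
network hyperparameters (epochs, optimizer, learning rate, hidden size,
SVM C/degree) are canonical; all are exposed in configuration.

On the synthetic benchmark (5 classes, 200 training windows per class,
noise 0.6, separation 0.35, seed 1) the held-out accuracies are
QDA 0.982, SVM 0.982, CNN 0.904, LSTM 0.988. The LSTM ≥ SVM ≥ CNN
ordering is asserted (with slack) as a regression property. QDA's
strong showing is a property of this data, not a general statement:
harmonic waveforms plus Gaussian noise make a PCA+QDA model close to
Bayes-optimal, whereas on real heterogeneous sensor data discriminant
analysis typically trails the other three. The tiny two-stage CNN is
also capacity-limited by design (it is the audited architecture, not a
tuned one).

## Synthetic data: what it emulates, what it does not

Each movement pattern has a per-channel waveform over cycle phase —
a mixture `(1−s)·common + s·specific` of unit-variance harmonic sums
(3 harmonics), with `s = pattern_separation` (default 0.6) dialing task
difficulty. Acceleration channels have unit scale, Euler channels scale
20. Emulated features of real data: variable cycle durations
(mean 1000 ms, sd 100 ms), a ~60 % stance fraction with the footplate
loaded in stance and unloaded in swing, additive Gaussian channel noise
(sd relative to channel scale), sporadic Euler-angle pulses, and
day-to-day wear drift as a per-channel affine perturbation
(offset/gain). Sessions can be "blocked" (all cycles of a pattern
consecutive) or "grouped" (short per-pattern groups cycling through all
patterns, like repeated experiment groups through a day); multi-day
protocols use grouped schedules so each session half contains every
pattern. A short unloaded lead-in and a loaded tail make the first and
last cycles detectable as rising pressure edges.

Not emulated: biomechanical realism (no physiological waveform shapes,
no correlated noise, no orientation-estimation error, no soft-tissue
artifacts), within-day fatigue drift, or sensor repositioning mid-day.
Passing tests therefore demonstrate the *mechanics* of the method —
segmentation, matching, selection, retraining, metrics — under
controlled difficulty, not field performance on human data.

## Experiment protocols and scenario design

* **Cross-day (D_i)**: train on each manually labeled day, test on a
  held-out day. With drift disabled, cross-day error matches within-day
  error; error tracks the injected drift magnitude, not the day index.
* **T vs AL**: T trains on day A and tests on day B's afternoon half;
  AL additionally builds templates from day A, auto-labels day B's
  morning half (threshold + transition suppression), retrains on the
  union, and tests on the same afternoon. Afternoon windows never enter
  training (asserted). The moderate-drift scenario (noise 0.3,
  separation 0.6, offset 0.3, gain 0.1) produces cross-day degradation
  that the AL retraining largely removes.
* **Template accumulation (AL1..ALm)**: level j pools the first j days
  into templates and manual training data. Pooling only helps where
  template quality actually limits pseudo-label accuracy; with
  well-separated patterns one day of templates already saturates SR, so
  the accumulation experiment runs in a harder regime (separation 0.25,
  noise 0.8, offset 0.6, gain 0.25) where single-day SR ≈ 0.82 rises to
  ≈ 0.95 with three pooled days and the median error falls accordingly.

Experiment sizes (10–12 cycles per pattern per day, 5–10 seeds) keep the
full suite and the acceptance script in the minutes range on one CPU;
the directional findings are stable at these sizes.

## Known limitations

* DTW is O(J·I) per template with no banding; fine at gait-cycle scale,
  wasteful for very long sequences.
* The transition-success metric and majority vote assume a steady
  prediction stream; heavily unbalanced phase durations shorten the
  effective vote window at phase starts.
* The unlabeled-day quantile rule fixes DR by construction and lets SR
  float; if a new day contained genuinely novel movement patterns the
  selector would still keep 90 % of cycles and mislabel them. The
  labeled `tune_k` protocol, run whenever same-day labels exist, is the
  guard against that failure mode.
* Model persistence uses pickle; artifacts are version-stamped but not
  portable across incompatible library versions.
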