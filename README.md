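# gaitmark

Movement-pattern recognition for leg-worn sensing: gait-cycle
segmentation from a footplate pressure channel, dynamic-time-warping
(DTW) template matching for **automatic pseudo-labeling** of new gait
cycles, and **incremental retraining** of window classifiers
(QDA / SVM / CNN / LSTM) on the selected pseudo-labels — with the full
evaluation layer (recognition error, confusion matrix, majority vote,
SR/DR trade-off) and a synthetic multi-day gait generator that provides
exact ground truth for every stage.

The package is aimed at researchers in wearable-sensor human movement
analysis who want a self-contained, testable implementation of the
template-based auto-labeling loop: label a day of data by hand once,
then let DTW matching against per-pattern templates label subsequent
days automatically and feed the trusted part of those labels back into
classifier training.

## Method

**Signals.** Each sample carries 10 IMU channels (triaxial acceleration,
pitch and roll for two units) plus a footplate pressure channel. Foot
contact (FC) and foot-off (FO) events are detected from pressure with a
hysteresis threshold pair; a gait cycle runs FC→FC and is split into
stance and swing at FO. Euler-angle channels pass through a limiting
filter that replaces single-sample pulses with the last valid sample.
Classifiers consume 300 ms windows advanced in 10 ms steps, trained
separately for stance and swing.

**DTW matching.** For a query cycle X = (x_1..x_J) and template
M = (m_1..m_I), the local cost is c(j, i) = ‖x_j − m_i‖², and the
cumulative cost follows

    D(j, i) = min( D(j−1, i−1), D(j−1, i), D(j, i−1) ) + c(j, i)

The cycle is assigned the pattern whose template minimizes the
normalized cost D(J, I)/K (K = warping-path length); normalization makes
costs comparable across cycles of different lengths.

**Templates.** Cycle lengths vary stride to stride, so each cycle is
resampled by cubic splines onto a fixed phase grid (stance and swing
separately, aligning FO across cycles) and z-scored; the template of
pattern h is the pointwise mean t_m = (1/K_h) Σ_n a_n of its K_h
normalized cycles — one template per pattern per subject.

**Selection and postprocessing.** A pseudo-label is trusted only when
its best cost is below a threshold k; `SR = N_C / N_I` (fraction of
selected cycles labeled correctly) trades off against
`DR = D_C / D_I` (fraction of cycles selected). When two adjacent
cycles disagree, a gait transition likely occurred in the swing phase,
and both cycles' swing windows are dropped from retraining.

**Evaluation.** `RE = N_mis / N_total × 100 %` over windows, a
row-percentage confusion matrix r_ij = s_ij / s_i × 100 %, a causal
5-point majority vote on the prediction stream, and a transition-success
rule (new pattern within the first five outputs after the event).

## Worked example

```python
import numpy as np
from gaitmark import (GeneratorConfig, generate_day, split_half, tune_k)
from gaitmark.experiments import run_T_vs_AL
from gaitmark.classifiers import ClassifierSpec

cfg = GeneratorConfig(noise_sd=0.3, day_shift_offset=0.3,
                      day_shift_gain=0.1, seed=0)
day1, _ = generate_day(cfg, n_cycles_per_pattern=12, day=0,
                       schedule="grouped")
day2, _ = generate_day(cfg, n_cycles_per_pattern=12, day=1,
                       schedule="grouped")

# pick the selection threshold by a same-day morning/afternoon cross-test
morning, afternoon = split_half(day1)
k_star, table = tune_k(morning, afternoon, dr_min=0.9)
print(f"tuned k = {k_star:.3f}  "
      f"SR = {table[table.k == k_star].sr.iloc[0]:.4f}  "
      f"DR = {table[table.k == k_star].dr.iloc[0]:.4f}")

# cross-day: plain training (T) vs auto-label retraining (AL)
report_T, report_AL = run_T_vs_AL(day1, day2, ClassifierSpec("QDA", seed=0))
print(f"cross-day RE (T)  = {report_T.re_percent:.2f}%")
print(f"cross-day RE (AL) = {report_AL.re_percent:.2f}%  "
      f"(pseudo-label SR = {report_AL.sr:.3f}, DR = {report_AL.dr:.3f})")
```

Output:

```
tuned k = 2.194  SR = 1.0000  DR = 0.9000
cross-day RE (T)  = 1.21%
cross-day RE (AL) = 1.01%  (pseudo-label SR = 1.000, DR = 0.900)
```

The tuned threshold selects 90 % of afternoon cycles with every selected
pseudo-label correct; retraining with auto-labeled morning data from the
test day lowers the cross-day window error rate relative to training on
the previous day alone.

A CLI mirrors the library (`gaitmark synthgait | preprocess | templates |
autolabel | train | evaluate | experiment`); every run writes a JSON
manifest with its inputs, configuration hash and seed.

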