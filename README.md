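# stridekit

Markerless gait-event detection from a single foot-mounted IMU, and
gait-cycle segmentation of synchronized surface EMG.

## The problem

Gait studies conducted in natural settings — walking over level ground,
ramps and stairs rather than on a treadmill — need a way to segment long
wearable-sensor recordings into traversals, terrain conditions and
individual strides without cameras or force plates. `stridekit`
implements a complete pipeline for one common setup: a foot-mounted IMU
sampled at 60 Hz (3-axis acceleration plus estimated y-position) recorded
synchronously with six-channel surface EMG at 1000 Hz (tibialis anterior,
medial gastrocnemius, vastus lateralis, rectus femoris, semitendinosus,
biceps femoris longus). It is aimed at researchers and students in
movement science who need a transparent, tunable reference pipeline, and
ships a seeded synthetic gait simulator so every stage can be exercised
and validated without any external recordings.

## The method

1. **Common timeline.** The kinematics are smoothed (centered moving
   average, 0.25 s) and linearly upsampled onto the EMG timeline,
   `y = y₁ + (x − x₁)(y₂ − y₁)/(x₂ − x₁)`; at 60 → 1000 Hz the EMG has
   ≈ 17× the samples of the IMU.
2. **Activity mask.** Windowed variance of x-axis acceleration is
   thresholded into a binary walking/rest signal; activity runs shorter
   than 6000 samples (6 s) are rejected as artifacts. Each surviving
   bout is a *half-trial* (one traversal of the course); directions
   alternate forward/reverse by protocol.
3. **Modality segmentation.** The course forces a sharp turn at each
   terrain change, so two prominent y-position extrema split every
   half-trial into three segments — ramp descent, level ground, stair
   ascent going out (RD, LGW, SA); stair descent, level ground, ramp
   ascent coming back (SD, LGW, RA). A 2000-sample (2 s) safety margin
   pads each segment before EMG extraction.
4. **Heel strikes.** The z-axis ground-reaction transient is isolated by
   a zero-phase envelope cascade — 7th-order Butterworth high-pass at
   9 Hz, half-wave rectification, 7th-order low-pass at 6 Hz — then
   cadence-constrained peak picking: peaks below a relative height floor
   are dropped and candidates closer than `(60/cadence)(1 − tol)` s are
   resolved in favour of the taller. Consecutive heel strikes bound one
   gait cycle (stride).
5. **EMG per cycle.** EMG is band-passed (order 4, 10–150 Hz, zero
   phase) and notch-filtered at the mains frequency, cut at the
   heel-strike samples, resampled onto a 0–100 % cycle axis (101 points)
   and summarized pointwise as mean ± SD across cycles.

All cadence, velocity, threshold and cutoff parameters are adjustable
through `PipelineConfig` (YAML-loadable), so the detector can be retuned
for slow, shuffling or otherwise atypical gait.

## Worked example

```python
from stridekit import SimConfig, simulate_trial, run_pipeline, match_events
import numpy as np

imu, emg, truth = simulate_trial(SimConfig(seed=1))
result = run_pipeline(imu, emg)
detected = np.sort(np.concatenate([e.times_s for e in result.events]))
report = match_events(detected, truth.all_hs_times_s, tol_s=0.05)
```

Running `python examples/01_simulate_and_detect.py` (which does exactly
this) prints:

```
half-trials detected : 4
modality segments    : 12
distinct modalities  : ['LGW', 'RA', 'RD', 'SA', 'SD']
heel strikes         : 120 detected / 120 true
precision / recall   : 1.000 / 1.000
mean |timing error|  : 2.4 ms
```

The default simulated protocol (two out-and-back trials) yields four
half-trials and twelve modality segments covering all five terrain
labels; all 120 simulated heel strikes are recovered within ±50 ms with
a mean timing error of 2.4 ms. The other scripts in `examples/` show the
designed filter responses, per-cycle muscle-activity summaries, and a
noise-robustness sweep.

A thin CLI wraps the same library:

```sh
stridekit simulate rec/ --seed 1
stridekit segment rec/ --out-dir results/
stridekit evaluate results/events.csv rec/ --tolerance 0.05
```

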