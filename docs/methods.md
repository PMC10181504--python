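# Methods

## Signal model and pipeline

The pipeline assumes one foot-mounted IMU (3-axis acceleration in m/s²
plus an estimated y-position trace, 60 Hz) recorded synchronously with
six surface-EMG channels (µV, 1000 Hz), uniformly sampled with no gaps.
Two physical facts carry the whole method:

* **Heel strike deposits impact-band energy.** The ground-reaction
  transient at initial contact is a short (~50 ms) burst of
  high-frequency vertical acceleration. A high-pass isolates that band,
  half-wave rectification demodulates its energy to baseband, and a
  low-pass smooths it into one bump per strike — a classic amplitude
  envelope detector. Heel strikes are then the envelope's peaks.
* **The protocol constrains the structure.** The subject walks a fixed
  course out and back, twice, resting in between, and turns sharply at
  each terrain change. Walking/rest alternation gives the half-trials;
  y-position extrema give the modality boundaries; direction follows
  protocol order (forward, reverse, …) rather than any data heuristic.

## Filtering conventions

All filters are Butterworth designs specified by their *single-pass*
order and -3 dB cutoffs, applied zero-phase (forward-backward), which
squares the magnitude response but adds no group delay — essential so
that envelope peaks stay aligned with the impacts that caused them, and
legitimate for post-hoc analysis where non-causality is free. The stated
cutoffs are therefore properties of the design, verified analytically
from the coefficients, not of the two-pass output.

Zero-phase application uses reflect ("even") padding of 3× the effective
polynomial order (2× the design order for a band-pass, the order itself
otherwise, 2 for the notch biquad) at each end; signals shorter than the
padding are rejected rather than silently filtered. The powerline notch
defaults to 60 Hz with quality factor q = 30 (bandwidth 2 Hz), switchable
to 50 Hz for other grids.

Fixed stage parameters, with defaults:

| stage | parameter | default | note |
|---|---|---|---|
| kinematic smoothing | centered moving-average window | 0.25 s | window forced odd (15 samples at 60 Hz) |
| activity energy | variance window | 0.5 s | forced odd: 501 samples at 1000 Hz |
| activity energy | threshold | 5 % of max windowed variance | unit-free; absolute override available |
| bout rejection | minimum bout | 6 s (6000 samples at 1 kHz) | shorter runs are artifacts |
| turn detection | prominence floor | 20 % of half-trial y-range | on maxima and minima |
| segment margin | padding | 2 s (2000 samples) | inclusion, not partitioning — padded neighbours may overlap |
| EMG band-pass | order 4, 10–150 Hz | — | physiological sEMG band |
| envelope cascade | HP order 7 @ 9 Hz; LP order 7 @ 6 Hz | — | both cutoffs exposed |
| peak picking | cadence 100 strides/min, tolerance 0.5, height 30 % of 95th percentile | — | refractory = (60/cadence)(1−tol) |
| normalization | 101 points (0–100 %) | — | field convention |
| event matching | tolerance ±50 ms | — | ≈ 3 IMU samples at 60 Hz |

The energy statistic is windowed *variance* (mean-removed mean square)
rather than raw mean square so a gravity offset on an acceleration
channel cannot saturate detection. The peak-height floor is relative to
the envelope's 95th percentile so the detector transfers across units
and datasets; an absolute override supports datasets with known
acceleration scales. An expected-velocity parameter is accepted and
recorded for protocol completeness but does not enter the detector;
only cadence constrains peak spacing.

Peak picking itself is implemented with `scipy.signal.find_peaks`,
whose distance-based suppression realizes exactly the intended rule —
candidates above the height floor, then greedy removal of neighbours
within the refractory interval in descending height order — and the
test suite holds it equal to an independent brute-force enumeration.

## Degenerate inputs and tie-breaks

A recording of pure rest produces zero half-trials and empty downstream
outputs, not an error. A flat (or all-negative) envelope yields zero
events. When turn detection finds fewer than two sufficiently prominent
extrema, the half-trial is split into equal thirds and each resulting
segment is flagged `fallback_used`; when more than two clear the floor,
the two most prominent win. Event matching is greedy nearest-first by
|Δt|; with stride periods far exceeding the matching tolerance the truth
windows are disjoint, where greedy provably attains the optimal
assignment — adversarial trains with events closer than twice the
tolerance can make greedy sub-optimal, which is accepted and tested only
in the physical regime. Indices are 0-based half-open `[start, end)`
everywhere; user-facing outputs are in seconds.

## The synthetic generator

`simulate_trial` emulates the experiment's structure, not its
biomechanics:

* **Course timeline** — `n_half_trials` (default 4) bouts of
  3 × `steps_per_modality` (default 10) strides at `cadence_spm`
  (default 100), separated by 10 s rests with 8 s lead-in/out. Heel
  strikes sit on the cadence grid with 5 ms Gaussian timing jitter.
* **x-acceleration** — a step-locked sinusoid (1 m/s² amplitude) plus
  band-limited noise during bouts, 0.02 m/s² noise at rest, mimicking
  the quasi-periodic anteroposterior acceleration of gait and giving
  the energy detector a realistic on/off contrast.
* **z-acceleration** — a Gabor-like damped oscillation per heel strike
  (5 m/s², 20 Hz centre, 50 ms width), placing its energy in the
  envelope detector's impact band, over 0.05 m/s² white noise.
* **y-position** — piecewise linear with a sharp vertex at each modality
  transition (slopes +1, −1, +1 within each bout), flat during rests.
* **EMG** — per muscle, a 20–150 Hz noise carrier gated by Gaussian
  envelopes centred at that muscle's configured cycle phase (TA at heel
  strike, gastrocnemius in late stance, quadriceps in early stance,
  hamstrings in terminal swing — textbook timing, supplied as config,
  not claimed as physiology), amplitude 60 µV over 6 µV background,
  with optional mains interference (off by default, amplitude and
  frequency exposed).

The IMU is generated at its native 60 Hz and pushed through the
pipeline's own upsampler, so interpolation is exercised exactly as on
real data. `degrade` adds white noise calibrated against the
walking-bout RMS for robustness sweeps.

What the simulator does **not** reproduce: gravity and orientation
drift, double-support dynamics, left-right asymmetry, amplitude
differences between terrains, EMG crosstalk, electrode-motion
artifacts, or pathological gait beyond cadence/amplitude knobs. Passing
tests therefore demonstrate that the pipeline's logic recovers the
structure it is designed for under realistic rates, counts and
noise — not clinical-grade accuracy on real recordings.

## Problem sizes used in validation

The repeated-detection studies run 100 seeded simulations at the default
conditions above (four half-trials, 120 heel strikes each) and require
precision and recall ≥ 0.95 at ±50 ms with mean absolute timing error
≤ 25 ms, and correct half-trial counts in ≥ 95 runs. Filter-design
checks evaluate the analytic response on grids of 2–4 × 10⁵ frequencies.
The cycle-count check simulates thirteen strides per segment and counts
the twelve cycles built from a level-ground segment's detected events.

## Known limitations

* Direction assignment is protocol-order only; a recording that starts
  mid-protocol or contains an odd number of bouts is flagged, not fixed.
* One sensor cannot disambiguate left from right foot strikes; cycles
  are same-limb strides by construction.
* Toe-off and stance/swing subphases are out of scope.
* Greedy event matching can under-match adversarial event trains packed
  tighter than twice the tolerance (see above).
* The fixed forward/reverse modality sequences assume the three-terrain
  course; other courses need their own label sequences.
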