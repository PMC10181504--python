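"""Synthetic gait-recording generator with ground-truth annotations.

Emulates the structure of an unconstrained walking experiment: a subject
traverses a course of three terrain modalities (ramp, level ground,
staircase) out and back, twice, with rests in between — four half-trials
per recording, three modality segments per half-trial, a sharp turn in
y-position at every modality transition, a vertical-acceleration impact
transient at every heel strike, and six sEMG channels whose bursts are
phase-locked to the gait cycle.

The IMU channels are generated at their native 60 Hz and the EMG at
1000 Hz, exactly as the recording hardware would produce them; the
analysis pipeline's own linear upsampler brings the IMU onto the common
1000 Hz timeline, so interpolation is exercised the same way it is on
real data.

Every random quantity derives from the config seed, so equal configs
give bitwise-equal recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .activity import FORWARD, REVERSE
from .emg import MUSCLES, EmgRecording
from .errors import InvalidParameterError
from .modality import FORWARD_SEQUENCE, REVERSE_SEQUENCE
from .signal_core import UniformSignal

__all__ = ["SimConfig", "GroundTruth", "simulate_trial", "degrade"]

#: Muscle burst timing as (center phase in [0, 1), width as phase s.d.).
#: Encodes textbook gait physiology as *defaults only*: TA fires around
#: heel strike (phase 0/1), the gastrocnemius in late stance, the
#: quadriceps (VL, RF) in early stance for weight acceptance, and the
#: hamstrings (SEM, BFL) in terminal swing ahead of the next strike.
DEFAULT_BURST_TABLE: dict[str, tuple[float, float]] = {
    "TA": (0.0, 0.06),
    "mGAST": (0.40, 0.08),
    "VL": (0.08, 0.06),
    "RF": (0.12, 0.07),
    "SEM": (0.90, 0.06),
    "BFL": (0.92, 0.06),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults describe a healthy adult walking an instrumented course:
    100 strides/min cadence, ten strides per terrain segment, 10 s rests
    between traversals, heel-strike transients of ~50 ms centred at
    20 Hz (inside the detector's impact band), and EMG bursts an order
    of magnitude above background.
    """

    seed: int = 0
    n_half_trials: int = 4
    steps_per_modality: int = 10
    cadence_spm: float = 100.0
    fs_imu: float = 60.0
    fs_emg: float = 1000.0
    rest_s: float = 10.0
    lead_s: float = 8.0
    # vertical-acceleration impact transient (Gabor-like wavelet)
    impact_amplitude: float = 5.0      # m/s^2
    impact_width_s: float = 0.05       # full width of the transient
    impact_freq_hz: float = 20.0       # centre frequency, in the HP passband
    hs_jitter_s: float = 0.005         # timing jitter s.d. around the cadence grid
    # noise levels
    accel_noise_sigma: float = 0.05    # m/s^2, white, all IMU accel channels
    walk_accel_sigma: float = 1.0      # m/s^2, band-limited, x-axis during bouts
    rest_accel_sigma: float = 0.02     # m/s^2, x-axis at rest
    emg_burst_amplitude: float = 60.0  # µV
    emg_noise_sigma: float = 6.0       # µV background
    mains_amplitude: float = 0.0       # µV, optional powerline interference
    mains_freq_hz: float = 60.0
    burst_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BURST_TABLE)
    )

    def __post_init__(self) -> None:
        if self.fs_imu <= 0 or self.fs_emg <= 0:
            raise InvalidParameterError("sampling rates must be positive")
        if self.n_half_trials < 1 or self.steps_per_modality < 1:
            raise InvalidParameterError("need >= 1 half-trial and >= 1 step per modality")
        if self.cadence_spm <= 0:
            raise InvalidParameterError("cadence must be positive")
        if self.rest_s * self.fs_emg <= 6000:
            raise InvalidParameterError(
                "rest between bouts must exceed the 6000-sample bout floor "
                "so bouts stay separable"
            )
        if self.bout_s * self.fs_emg <= 6000:
            raise InvalidParameterError(
                "bout too short for the requested steps: it would be "
                "rejected by the 6000-sample activity floor"
            )
        missing = set(MUSCLES) - set(self.burst_table)
        if missing:
            raise InvalidParameterError(f"burst table missing muscles: {sorted(missing)}")

    @property
    def stride_s(self) -> float:
        """Nominal heel-strike spacing, seconds."""
        return 60.0 / self.cadence_spm

    @property
    def segment_s(self) -> float:
        return self.steps_per_modality * self.stride_s

    @property
    def bout_s(self) -> float:
        return 3 * self.segment_s

    @property
    def total_s(self) -> float:
        n = self.n_half_trials
        return 2 * self.lead_s + n * self.bout_s + (n - 1) * self.rest_s


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    bout_intervals_s: list[tuple[float, float]]
    directions: list[str]
    turn_times_s: list[tuple[float, float]]
    segments: list[dict]            # {half_trial, label, start_s, end_s}
    hs_times_s: list[np.ndarray]    # per modality segment, strictly increasing
    burst_table: dict[str, tuple[float, float]]

    @property
    def all_hs_times_s(self) -> np.ndarray:
        if not self.hs_times_s:
            return np.array([])
        return np.concatenate(self.hs_times_s)

    def to_dict(self) -> dict:
        return {
            "bout_intervals_s": [list(b) for b in self.bout_intervals_s],
            "directions": list(self.directions),
            "turn_times_s": [list(t) for t in self.turn_times_s],
            "segments": self.segments,
            "hs_times_s": [t.tolist() for t in self.hs_times_s],
            "burst_table": {k: list(v) for k, v in self.burst_table.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            bout_intervals_s=[tuple(b) for b in d["bout_intervals_s"]],
            directions=list(d["directions"]),
            turn_times_s=[tuple(t) for t in d["turn_times_s"]],
            segments=list(d["segments"]),
            hs_times_s=[np.asarray(t) for t in d["hs_times_s"]],
            burst_table={k: tuple(v) for k, v in d["burst_table"].items()},
        )


def _layout(config: SimConfig, rng: np.random.Generator):
    """Course timeline: bouts, turns, segments and jittered HS times."""
    bouts, directions, turns, segments, hs_lists = [], [], [], [], []
    t = config.lead_s
    for ht in range(config.n_half_trials):
        direction = FORWARD if ht % 2 == 0 else REVERSE
        labels = FORWARD_SEQUENCE if direction == FORWARD else REVERSE_SEQUENCE
        bout_start = t
        seg_bounds = [bout_start + k * config.segment_s for k in range(4)]
        turns.append((seg_bounds[1], seg_bounds[2]))
        for k, label in enumerate(labels):
            seg_start, seg_end = seg_bounds[k], seg_bounds[k + 1]
            segments.append(
                {
                    "half_trial": ht,
                    "label": label,
                    "start_s": seg_start,
                    "end_s": seg_end,
                }
            )
            # HS grid: strides at the cadence spacing, first strike half a
            # stride in so transients sit fully inside the segment
            grid = seg_start + (0.5 + np.arange(config.steps_per_modality)) * config.stride_s
            if config.hs_jitter_s > 0:
                jitter = rng.normal(0.0, config.hs_jitter_s, grid.size)
                # keep jitter small enough to preserve strict ordering
                jitter = np.clip(jitter, -0.4 * config.stride_s, 0.4 * config.stride_s)
                grid = np.sort(grid + jitter)
            hs_lists.append(grid)
        bouts.append((bout_start, seg_bounds[3]))
        directions.append(direction)
        t = seg_bounds[3] + config.rest_s
    return bouts, directions, turns, segments, hs_lists


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise restricted to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white)
    std = shaped.std()
    return shaped / std if std > 0 else shaped


def _impact_wavelet(t: np.ndarray, center: float, config: SimConfig) -> np.ndarray:
    """Gabor-like damped oscillation modeling the ground-reaction transient."""
    sigma = config.impact_width_s / 4.0
    dt = t - center
    return (
        config.impact_amplitude
        * np.exp(-0.5 * (dt / sigma) ** 2)
        * np.cos(2 * np.pi * config.impact_freq_hz * dt)
    )


def simulate_trial(
    config: SimConfig,
) -> tuple[dict[str, UniformSignal], EmgRecording, GroundTruth]:
    """Generate one complete recording plus its ground truth.

    Returns ``(imu, emg, truth)`` where ``imu`` holds 60 Hz channels
    ``accel_x``, ``accel_y``, ``accel_z`` and ``pos_y``, and ``emg`` is a
    six-muscle 1000 Hz recording.
    """
    rng = np.random.default_rng(config.seed)
    bouts, directions, turns, segments, hs_lists = _layout(config, rng)

    n_imu = int(round(config.total_s * config.fs_imu)) + 1
    t_imu = np.arange(n_imu) / config.fs_imu
    n_emg = int(round(config.total_s * config.fs_emg)) + 1
    t_emg = np.arange(n_emg) / config.fs_emg

    in_bout = np.zeros(n_imu, dtype=bool)
    for start, end in bouts:
        in_bout |= (t_imu >= start) & (t_imu < end)

    # x-axis: quasi-periodic step-locked oscillation plus band-limited
    # noise while walking, near silence at rest — the energy detector's
    # input.  The periodic component keeps windowed energy steadily high
    # throughout a bout, as anteroposterior gait acceleration is.
    accel_x = rng.normal(0.0, config.rest_accel_sigma, n_imu)
    step_hz = 1.0 / config.stride_s
    walk_noise = _bandlimited_noise(rng, n_imu, config.fs_imu, (0.5, 10.0))
    phase = rng.uniform(0, 2 * np.pi)
    walk = np.sin(2 * np.pi * step_hz * t_imu + phase) + 0.3 * walk_noise
    accel_x[in_bout] += config.walk_accel_sigma * walk[in_bout]

    # y-axis: small noise only (not used by the pipeline, present for realism)
    accel_y = rng.normal(0.0, config.accel_noise_sigma, n_imu)

    # z-axis: impact transient at every heel strike + white noise
    accel_z = rng.normal(0.0, config.accel_noise_sigma, n_imu)
    for hs in hs_lists:
        for center in hs:
            lo = max(0, int((center - 3 * config.impact_width_s) * config.fs_imu))
            hi = min(n_imu, int((center + 3 * config.impact_width_s) * config.fs_imu) + 1)
            accel_z[lo:hi] += _impact_wavelet(t_imu[lo:hi], center, config)

    # y-position: piecewise linear with a sharp vertex at each modality
    # transition (up, back down, up again), flat during rests
    pos_y = np.zeros(n_imu)
    slope_pattern = (1.0, -1.0, 1.0)
    level = 0.0
    prev_end = 0.0
    for (bout_start, bout_end), (turn1, turn2) in zip(bouts, turns):
        pos_y[(t_imu >= prev_end) & (t_imu < bout_start)] = level
        seg_edges = [bout_start, turn1, turn2, bout_end]
        for k in range(3):
            m = (t_imu >= seg_edges[k]) & (t_imu < seg_edges[k + 1])
            pos_y[m] = level + slope_pattern[k] * (t_imu[m] - seg_edges[k])
            level += slope_pattern[k] * (seg_edges[k + 1] - seg_edges[k])
        prev_end = bout_end
    pos_y[t_imu >= prev_end] = level

    imu = {
        "accel_x": UniformSignal(accel_x, config.fs_imu, "accel_x"),
        "accel_y": UniformSignal(accel_y, config.fs_imu, "accel_y"),
        "accel_z": UniformSignal(accel_z, config.fs_imu, "accel_z"),
        "pos_y": UniformSignal(pos_y, config.fs_imu, "pos_y"),
    }

    # EMG: per muscle, a 20–150 Hz carrier gated by Gaussian burst
    # envelopes phase-locked to the gait cycle, over background noise
    channels: dict[str, UniformSignal] = {}
    for muscle in MUSCLES:
        phase_mu, phase_sd = config.burst_table[muscle]
        envelope = np.zeros(n_emg)
        for seg_hs in hs_lists:
            for k in range(len(seg_hs) - 1):
                start, end = seg_hs[k], seg_hs[k + 1]
                dur = end - start
                center = start + phase_mu * dur
                sd = phase_sd * dur
                lo = max(0, int((center - 4 * sd) * config.fs_emg))
                hi = min(n_emg, int((center + 4 * sd) * config.fs_emg) + 1)
                envelope[lo:hi] += np.exp(
                    -0.5 * ((t_emg[lo:hi] - center) / sd) ** 2
                )
        carrier = _bandlimited_noise(rng, n_emg, config.fs_emg, (20.0, 150.0))
        x = config.emg_burst_amplitude * envelope * carrier
        x += rng.normal(0.0, config.emg_noise_sigma, n_emg)
        if config.mains_amplitude > 0:
            x += config.mains_amplitude * np.sin(2 * np.pi * config.mains_freq_hz * t_emg)
        channels[muscle] = UniformSignal(x, config.fs_emg, muscle)

    emg = EmgRecording(channels, subject="sim", trial=f"seed{config.seed}")
    truth = GroundTruth(
        bout_intervals_s=bouts,
        directions=directions,
        turn_times_s=turns,
        segments=segments,
        hs_times_s=hs_lists,
        burst_table=dict(config.burst_table),
    )
    return imu, emg, truth


def degrade(
    signal: UniformSignal,
    snr_db: float,
    bout_intervals_s: list[tuple[float, float]],
    seed: int = 0,
) -> UniformSignal:
    """Add white noise scaled to a target SNR over the walking bouts.

    The reference power is the mean-removed mean square of the signal
    within the bouts; noise power is reference / 10^(snr_db/10).
    """
    if not np.isfinite(snr_db):
        raise InvalidParameterError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    t = signal.times
    in_bout = np.zeros(len(signal), dtype=bool)
    for start, end in bout_intervals_s:
        in_bout |= (t >= start) & (t < end)
    ref = signal.values[in_bout] if in_bout.any() else signal.values
    power = float(np.mean((ref - ref.mean()) ** 2))
    noise_sd = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return signal.with_values(signal.values + rng.normal(0.0, noise_sd, len(signal)))
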