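"""Surface-EMG conditioning, segmentation and per-cycle summaries.

Raw sEMG from six lower-limb muscles — tibialis anterior (TA), medial
gastrocnemius (mGAST), vastus lateralis (VL), rectus femoris (RF),
semitendinosus (SEM) and biceps femoris longus (BFL) — is band-passed to
the physiological 10–150 Hz band, notched at the mains frequency, then
cut by half-trial, modality segment and gait cycle.  Cycles of unequal
duration are compared by resampling each onto a common 0–100 % gait-cycle
axis (101 points, the field's convention) and summarising pointwise with
mean and sample standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .heelstrike import GaitCycle
from .modality import ModalitySegment
from .activity import HalfTrial
from .signal_core import FilterSpec, UniformSignal, apply_butterworth, upsample_linear

__all__ = [
    "MUSCLES",
    "EmgRecording",
    "CycleMatrix",
    "preprocess_emg",
    "cut_by_interval",
    "segment_by_cycles",
    "time_normalize",
    "summarize_cycles",
]

log = logging.getLogger(__name__)

#: Canonical muscle set and channel order.
MUSCLES = ("TA", "mGAST", "VL", "RF", "SEM", "BFL")

DEFAULT_BANDPASS_HZ = (10.0, 150.0)
DEFAULT_BANDPASS_ORDER = 4
DEFAULT_NOTCH_HZ = 60.0
DEFAULT_NOTCH_Q = 30.0
DEFAULT_N_NORM = 101
#: Low-pass cutoff (Hz) of the optional rectified-envelope summary.
DEFAULT_SUMMARY_ENVELOPE_HZ = 6.0


@dataclass(frozen=True)
class EmgRecording:
    """Six synchronized sEMG channels at a common sampling rate."""

    channels: dict[str, UniformSignal]
    subject: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise InvalidInputError("recording needs at least one channel")
        unknown = set(self.channels) - set(MUSCLES)
        if unknown:
            raise InvalidInputError(f"unknown muscle labels: {sorted(unknown)}")
        lengths = {len(sig) for sig in self.channels.values()}
        rates = {sig.fs for sig in self.channels.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise InvalidInputError("all channels must share length and sampling rate")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(m for m in MUSCLES if m in self.channels)

    def map_channels(self, fn) -> "EmgRecording":
        return EmgRecording(
            {name: fn(sig) for name, sig in self.channels.items()},
            self.subject,
            self.trial,
        )


@dataclass(frozen=True)
class CycleMatrix:
    """Per-muscle cycles x n_norm amplitude grids on a 0–100 % axis."""

    data: dict[str, np.ndarray]
    cycles: list[GaitCycle]
    n_norm: int

    def __post_init__(self) -> None:
        for muscle, grid in self.data.items():
            if grid.shape != (len(self.cycles), self.n_norm):
                raise InvalidInputError(
                    f"{muscle}: grid shape {grid.shape} != "
                    f"({len(self.cycles)}, {self.n_norm})"
                )

    @property
    def phase_percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_norm)

    def to_frame(self, muscle: str) -> pd.DataFrame:
        """Rows = cycles, columns = normalized-phase percentages."""
        return pd.DataFrame(
            self.data[muscle],
            index=[c.index for c in self.cycles],
            columns=np.round(self.phase_percent, 1),
        )


def preprocess_emg(
    raw: EmgRecording,
    bandpass_hz: tuple[float, float] = DEFAULT_BANDPASS_HZ,
    bandpass_order: int = DEFAULT_BANDPASS_ORDER,
    notch_hz: float = DEFAULT_NOTCH_HZ,
    notch_q: float = DEFAULT_NOTCH_Q,
) -> EmgRecording:
    """Band-pass then notch every channel, zero-phase, length preserved.

    The band-pass (order 4, 10–150 Hz by default) removes motion-artifact
    drift and out-of-band noise; the notch removes powerline interference
    (60 Hz for North-American recordings, set 50 Hz elsewhere).
    """
    if raw.fs <= 2 * bandpass_hz[1]:
        raise InvalidParameterError(
            f"sampling rate {raw.fs} Hz too low for a {bandpass_hz[1]} Hz band edge"
        )
    bp = FilterSpec("bandpass", bandpass_order, bandpass_hz)
    notch = FilterSpec("notch", 2, (notch_hz,), q=notch_q)

    def condition(sig: UniformSignal) -> UniformSignal:
        return apply_butterworth(apply_butterworth(sig, bp), notch)

    return raw.map_channels(condition)


def cut_by_interval(
    emg: EmgRecording, interval: HalfTrial | ModalitySegment
) -> EmgRecording:
    """Exact sample-index crop of every channel on the shared timeline.

    Modality segments are cut at their padded (safety-margin) bounds when
    present, half-trials at their stated bounds.
    """
    if isinstance(interval, ModalitySegment):
        start, end = interval.extraction_bounds
    else:
        start, end = interval.start, interval.end
    if not (0 <= start < end <= emg.n_samples):
        raise InvalidInputError(
            f"interval [{start}, {end}) outside recording of {emg.n_samples} samples"
        )
    return emg.map_channels(lambda sig: sig.crop(start, end))


def segment_by_cycles(
    emg: EmgRecording, cycles: list[GaitCycle]
) -> list[EmgRecording]:
    """One crop per gait cycle, boundaries at the heel-strike samples.

    Cycle times are mapped to sample indices by rounding; crops are
    half-open so adjacent cycles share exactly one boundary index.
    Cycles falling outside the recording are skipped with a warning.
    """
    t0 = next(iter(emg.channels.values())).t0
    crops: list[EmgRecording] = []
    n_skipped = 0
    for cycle in cycles:
        start = int(round((cycle.start_s - t0) * emg.fs))
        end = int(round((cycle.end_s - t0) * emg.fs))
        if start < 0 or end > emg.n_samples or start >= end:
            n_skipped += 1
            continue
        crops.append(emg.map_channels(lambda sig: sig.crop(start, end)))
    if n_skipped:
        log.warning("skipped %d gait cycles outside the recording bounds", n_skipped)
    return crops


def time_normalize(
    crops: list[EmgRecording],
    cycles: list[GaitCycle] | None = None,
    n_norm: int = DEFAULT_N_NORM,
) -> CycleMatrix:
    """Resample each cycle crop onto ``n_norm`` points of 0–100 % phase.

    Linear interpolation (the same primitive used for IMU upsampling)
    maps each crop's own duration onto the normalized axis, so cycles of
    different length become comparable rows.  Crops shorter than two
    samples are skipped with a warning.
    """
    if n_norm < 2:
        raise InvalidParameterError("n_norm must be >= 2")
    kept_crops: list[EmgRecording] = []
    kept_cycles: list[GaitCycle] = []
    for i, crop in enumerate(crops):
        if crop.n_samples < 2:
            log.warning("skipping cycle crop %d with < 2 samples", i)
            continue
        kept_crops.append(crop)
        if cycles is not None:
            kept_cycles.append(cycles[i])
    muscles = kept_crops[0].muscles if kept_crops else MUSCLES
    data = {
        muscle: np.empty((len(kept_crops), n_norm)) for muscle in muscles
    }
    for row, crop in enumerate(kept_crops):
        for muscle in muscles:
            sig = crop.channels[muscle]
            if len(sig) >= n_norm:
                # interpolate onto the normalized grid directly
                t = np.linspace(0.0, sig.duration, n_norm)
                data[muscle][row] = np.interp(t, np.arange(len(sig)) / sig.fs, sig.values)
            else:
                data[muscle][row] = upsample_linear(sig, n_norm).values
    if cycles is None:
        kept_cycles = []
        for i, crop in enumerate(kept_crops):
            sig = crop.channels[muscles[0]]
            kept_cycles.append(GaitCycle(sig.t0, sig.t0 + len(sig) / sig.fs, index=i))
    return CycleMatrix(data, kept_cycles, n_norm)


def summarize_cycles(
    matrix: CycleMatrix,
    rectified_envelope: bool = False,
    envelope_cutoff_hz: float = DEFAULT_SUMMARY_ENVELOPE_HZ,
    envelope_order: int = 4,
) -> pd.DataFrame:
    """Pointwise mean and sample SD (ddof=1) per muscle across cycles.

    With ``rectified_envelope`` each row is full-wave rectified and
    low-passed before averaging, giving amplitude-profile summaries
    instead of raw filtered-signal summaries.  A single-row matrix
    reports SD 0 with ``sd_defined=False``.
    """
    if not matrix.cycles:
        raise InvalidInputError("need at least one cycle to summarize")
    n_rows = len(matrix.cycles)
    frames = []
    for muscle, grid in matrix.data.items():
        rows = grid
        if rectified_envelope:
            # phase axis spans one cycle; use the mean cycle duration to
            # give the normalized rows a nominal sampling rate
            mean_dur = float(np.mean([c.duration_s for c in matrix.cycles]))
            fs_norm = (matrix.n_norm - 1) / mean_dur
            lp = FilterSpec("lowpass", envelope_order, (envelope_cutoff_hz,))
            rows = np.vstack(
                [
                    apply_butterworth(
                        UniformSignal(np.abs(r), fs_norm, muscle), lp
                    ).values
                    for r in grid
                ]
            )
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=1) if n_rows > 1 else np.zeros(matrix.n_norm)
        frames.append(
            pd.DataFrame(
                {
                    "muscle": muscle,
                    "phase_percent": matrix.phase_percent,
                    "mean": mean,
                    "sd": sd,
                    "n_cycles": n_rows,
                    "sd_defined": n_rows > 1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
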