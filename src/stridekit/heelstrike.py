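"""Heel-strike detection from vertical acceleration.

A heel strike deposits a short burst of high-frequency energy into the
z-axis accelerometer (the ground-reaction transient).  The detector is an
amplitude-envelope cascade — seventh-order Butterworth high-pass at 9 Hz,
half-wave rectification, seventh-order low-pass at 6 Hz, all zero-phase —
followed by cadence-constrained peak picking: rectification demodulates
the impact-band energy to baseband, the low-pass leaves one smooth bump
per strike, and peaks closer together than the expected stride period
(scaled by a tolerance) are resolved in favour of the taller one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidParameterError
from .signal_core import FilterSpec, UniformSignal, apply_butterworth, half_wave_rectify

__all__ = [
    "CadenceParams",
    "GaitEventSeries",
    "GaitCycle",
    "hs_envelope",
    "detect_heel_strikes",
    "build_gait_cycles",
]

#: Envelope cascade cutoffs (Hz). The high-pass isolates the impact band,
#: the low-pass smooths the rectified energy into one bump per strike.
DEFAULT_HP_CUTOFF_HZ = 9.0
DEFAULT_LP_CUTOFF_HZ = 6.0
DEFAULT_ENVELOPE_ORDER = 7


@dataclass(frozen=True)
class CadenceParams:
    """Tunables of the peak picker.

    ``expected_cadence_spm`` sets the nominal stride rate; candidate
    peaks closer than ``(60/cadence) * (1 - cadence_tolerance)`` seconds
    are mutually exclusive.  ``min_peak_height`` is relative to the 95th
    percentile of the envelope, so the detector transfers across units
    and datasets; ``abs_peak_height`` overrides it with an absolute
    acceleration-envelope level when set.  ``expected_velocity_mps`` is
    accepted for protocol completeness but does not enter the detector.
    """

    expected_cadence_spm: float = 100.0
    cadence_tolerance: float = 0.5
    min_peak_height: float = 0.3
    abs_peak_height: float | None = None
    expected_velocity_mps: float | None = None

    def __post_init__(self) -> None:
        if not self.expected_cadence_spm > 0:
            raise InvalidParameterError("cadence must be > 0")
        if not 0 < self.cadence_tolerance < 1:
            raise InvalidParameterError("cadence_tolerance must be in (0, 1)")
        if not 0 < self.min_peak_height <= 1:
            raise InvalidParameterError("min_peak_height must be in (0, 1]")

    @property
    def refractory_s(self) -> float:
        """Minimum spacing between accepted events, seconds."""
        return (60.0 / self.expected_cadence_spm) * (1.0 - self.cadence_tolerance)


@dataclass(frozen=True)
class GaitEventSeries:
    """Strictly increasing heel-strike times with their provenance."""

    times_s: np.ndarray
    segment_label: str = ""
    params: CadenceParams = field(default_factory=CadenceParams)

    def __post_init__(self) -> None:
        arr = np.asarray(self.times_s, dtype=float)
        if arr.size and not np.all(np.diff(arr) > 0):
            raise InvalidParameterError("event times must be strictly increasing")
        object.__setattr__(self, "times_s", arr)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class GaitCycle:
    """One stride: [start_s, end_s) between consecutive heel strikes."""

    start_s: float
    end_s: float
    label: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise InvalidParameterError("gait cycle must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def hs_envelope(
    accel_z: UniformSignal,
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ,
    lp_cutoff_hz: float = DEFAULT_LP_CUTOFF_HZ,
    order: int = DEFAULT_ENVELOPE_ORDER,
) -> UniformSignal:
    """High-pass -> half-wave rectify -> low-pass amplitude envelope.

    Both filters are zero-phase, so envelope bumps stay time-aligned with
    the impacts that caused them.  The output is not guaranteed
    nonnegative: a zero-phase IIR low-pass can undershoot slightly.
    """
    hp = FilterSpec("highpass", order, (hp_cutoff_hz,))
    lp = FilterSpec("lowpass", order, (lp_cutoff_hz,))
    x = apply_butterworth(accel_z, hp)
    x = half_wave_rectify(x)
    return apply_butterworth(x, lp)


def detect_heel_strikes(
    envelope: UniformSignal, params: CadenceParams | None = None, label: str = ""
) -> GaitEventSeries:
    """Cadence-constrained peak picking on the impact envelope.

    Candidate peaks must reach ``min_peak_height`` times the envelope's
    95th percentile (or the absolute override); peaks violating the
    refractory spacing are suppressed in descending height order, so of
    two close candidates the taller wins.  A flat or empty envelope
    yields an empty series.
    """
    params = params or CadenceParams()
    x = envelope.values
    if params.abs_peak_height is not None:
        height = params.abs_peak_height
    else:
        height = params.min_peak_height * float(np.percentile(x, 95))
    # a sparse envelope can have a zero/negative 95th percentile; clamp the
    # floor so only strictly positive bumps qualify and a flat or
    # all-negative envelope yields no events
    height = max(height, np.finfo(float).tiny)
    distance = max(1, int(np.ceil(params.refractory_s * envelope.fs)))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    times = envelope.t0 + peaks / envelope.fs
    return GaitEventSeries(times, label, params)


def build_gait_cycles(events: GaitEventSeries, label: str = "") -> list[GaitCycle]:
    """Tile consecutive heel strikes into (n_events - 1) gait cycles."""
    t = events.times_s
    label = label or events.segment_label
    return [
        GaitCycle(float(t[k]), float(t[k + 1]), label=label, index=k)
        for k in range(len(t) - 1)
    ]
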