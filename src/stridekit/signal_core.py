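"""Shared signal primitives: uniform time series, smoothing, linear
upsampling, zero-phase Butterworth filtering and rectification.

All downstream stages (activity masking, modality splitting, heel-strike
envelope detection, EMG conditioning) are built on these four operations.
Filters are specified by their *single-pass* design (order and -3 dB
cutoffs); zero-phase application runs the designed filter forward and
backward, which squares the magnitude response but leaves the stated
cutoffs verifiable on the design itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "UniformSignal",
    "FilterSpec",
    "moving_average",
    "upsample_linear",
    "apply_butterworth",
    "half_wave_rectify",
    "design_filter",
    "frequency_response",
]


@dataclass(frozen=True)
class UniformSignal:
    """One channel of uniformly sampled data.

    Parameters
    ----------
    values
        Ordered samples in the channel's native units (m/s², µV, m, ...).
    fs
        Sampling rate in Hz; must be positive.
    label
        Channel role tag (e.g. ``"accel_z"`` or ``"TA"``).
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("signal must be a 1-D array with >= 1 sample")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"channel {self.label!r} contains non-finite values")
        if not (self.fs > 0):
            raise InvalidParameterError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span between first and last sample, (n-1)/fs seconds."""
        return (len(self) - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray) -> "UniformSignal":
        return replace(self, values=values)

    def crop(self, start: int, end: int) -> "UniformSignal":
        """Half-open sample-index crop [start, end)."""
        if not (0 <= start < end <= len(self)):
            raise InvalidInputError(
                f"crop [{start}, {end}) out of bounds for length {len(self)}"
            )
        return UniformSignal(
            self.values[start:end], self.fs, self.label, self.t0 + start / self.fs
        )


@dataclass(frozen=True)
class FilterSpec:
    """Single-pass Butterworth (or notch) design parameters.

    ``cutoffs_hz`` holds one frequency for lowpass/highpass/notch and two
    increasing frequencies for bandpass.  ``q`` is the notch quality
    factor (bandwidth = f0/q).  ``zero_phase`` selects forward-backward
    application, which doubles the effective attenuation but keeps the
    stated cutoffs as the design's -3 dB points.
    """

    kind: str
    order: int
    cutoffs_hz: tuple[float, ...]
    zero_phase: bool = True
    q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass", "notch"):
            raise InvalidParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidParameterError("filter order must be >= 1")
        cutoffs = tuple(float(c) for c in np.atleast_1d(self.cutoffs_hz))
        if self.kind == "bandpass":
            if len(cutoffs) != 2 or not cutoffs[0] < cutoffs[1]:
                raise InvalidParameterError("bandpass needs two increasing cutoffs")
        elif len(cutoffs) != 1:
            raise InvalidParameterError(f"{self.kind} takes exactly one cutoff")
        if any(c <= 0 for c in cutoffs):
            raise InvalidParameterError("cutoffs must be positive")
        if self.kind == "notch" and not (self.q > 0):
            raise InvalidParameterError("notch quality factor must be > 0")
        object.__setattr__(self, "cutoffs_hz", cutoffs)

    @property
    def effective_order(self) -> int:
        """Polynomial order of the realized transfer function."""
        if self.kind == "bandpass":
            return 2 * self.order
        if self.kind == "notch":
            return 2
        return self.order

    def validate_against(self, fs: float) -> None:
        nyq = fs / 2.0
        if any(c >= nyq for c in self.cutoffs_hz):
            raise InvalidParameterError(
                f"cutoffs {self.cutoffs_hz} must lie strictly below Nyquist ({nyq} Hz)"
            )


def design_filter(spec: FilterSpec, fs: float) -> np.ndarray:
    """Return second-order sections for the single-pass design."""
    spec.validate_against(fs)
    if spec.kind == "notch":
        b, a = sps.iirnotch(spec.cutoffs_hz[0], spec.q, fs=fs)
        return sps.tf2sos(b, a)
    btype = {"lowpass": "lowpass", "highpass": "highpass", "bandpass": "bandpass"}[spec.kind]
    wn = spec.cutoffs_hz if spec.kind == "bandpass" else spec.cutoffs_hz[0]
    return sps.butter(spec.order, wn, btype=btype, fs=fs, output="sos")


def frequency_response(
    spec: FilterSpec, fs: float, freqs_hz: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass magnitude response of the designed filter.

    Computed analytically from the coefficients, independent of any data.
    Returns ``(freqs_hz, |H|)``.
    """
    sos = design_filter(spec, fs)
    if freqs_hz is None:
        w, h = sps.sosfreqz(sos, worN=65536, fs=fs)
    else:
        w, h = sps.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=fs)
    return w, np.abs(h)


def moving_average(signal: UniformSignal, window_len: int) -> UniformSignal:
    """Centered moving-average smoother with edge windows truncated.

    ``window_len`` must be odd so the window centers on each sample; near
    the edges the mean is taken over however many samples fall inside the
    signal, so the output has the same length as the input.
    """
    n = len(signal)
    if window_len < 1 or window_len % 2 == 0:
        raise InvalidParameterError(f"window_len must be odd and >= 1, got {window_len}")
    if window_len > n:
        raise InvalidParameterError(f"window_len {window_len} exceeds signal length {n}")
    if window_len == 1:
        return signal
    kernel = np.ones(window_len)
    sums = np.convolve(signal.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return signal.with_values(sums / counts)


def upsample_linear(signal: UniformSignal, target_n: int) -> UniformSignal:
    """Linearly interpolate onto ``target_n`` samples over the same span.

    Each output value y at query time x is obtained from the bracketing
    input samples (x1, y1), (x2, y2) as
    ``y = y1 + (x - x1) * (y2 - y1) / (x2 - x1)``, so input samples are
    reproduced exactly and interior values lie on the connecting chords.
    The output rate is (target_n - 1)/duration.
    """
    n = len(signal)
    if n < 2:
        raise InvalidInputError("need >= 2 samples to interpolate")
    if target_n < n:
        raise InvalidParameterError(
            f"target_n {target_n} < input length {n}: downsampling unsupported"
        )
    if target_n == n:
        return signal
    duration = signal.duration
    t_in = np.arange(n) / signal.fs
    t_out = np.linspace(0.0, duration, target_n)
    values = np.interp(t_out, t_in, signal.values)
    return UniformSignal(values, (target_n - 1) / duration, signal.label, signal.t0)


def _padlen(spec: FilterSpec, n: int) -> int:
    pad = 3 * spec.effective_order
    if pad >= n:
        raise InvalidInputError(
            f"signal of {n} samples too short for zero-phase padding ({pad})"
        )
    return pad


def apply_butterworth(signal: UniformSignal, spec: FilterSpec) -> UniformSignal:
    """Apply the designed filter; forward-backward when ``zero_phase``.

    Zero-phase application uses reflect ("even") padding of 3x the
    effective filter order at each end, so a symmetric input maps to a
    symmetric output with no group delay.
    """
    sos = design_filter(spec, signal.fs)
    x = signal.values
    if spec.zero_phase:
        pad = _padlen(spec, len(signal))
        y = sps.sosfiltfilt(sos, x, padtype="even", padlen=pad)
    else:
        y = sps.sosfilt(sos, x)
    return signal.with_values(y)


def half_wave_rectify(signal: UniformSignal) -> UniformSignal:
    """Clamp negative samples to zero: out[i] = max(in[i], 0)."""
    return signal.with_values(np.maximum(signal.values, 0.0))
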