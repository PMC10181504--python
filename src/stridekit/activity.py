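"""Walking-activity detection from x-axis acceleration.

The smoothed, upsampled accelerometer trace is turned into a binary
walking/rest mask by thresholding windowed signal energy; short bouts are
rejected as motion artifacts; the surviving bouts become half-trials
(one traversal of the course in one direction) with directions assigned
from the experimental protocol order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .signal_core import UniformSignal, moving_average

__all__ = [
    "ActivityMask",
    "HalfTrial",
    "windowed_variance",
    "detect_activity",
    "remove_short_bouts",
    "extract_half_trials",
    "assign_directions",
]

log = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

#: Bout-length floor on the 1000 Hz timeline: activity shorter than this
#: (6 s) is treated as a motion artifact, not walking.
DEFAULT_MIN_BOUT_SAMPLES = 6000


@dataclass(frozen=True)
class ActivityMask:
    """Per-sample binary walking flag on the upsampled timeline."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int8)
        if not np.isin(arr, (0, 1)).all():
            raise InvalidParameterError("mask values must be 0 or 1")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def runs(self) -> list[tuple[int, int]]:
        """Maximal runs of 1s as half-open (start, end) index pairs."""
        padded = np.concatenate(([0], self.values, [0]))
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return list(zip(starts.tolist(), ends.tolist()))


@dataclass(frozen=True)
class HalfTrial:
    """One traversal of the course: [start, end) samples plus direction."""

    start: int
    end: int
    direction: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(f"bad half-trial bounds [{self.start}, {self.end})")
        if self.direction not in (None, FORWARD, REVERSE):
            raise InvalidParameterError(f"bad direction {self.direction!r}")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def windowed_variance(signal: UniformSignal, window_len: int) -> np.ndarray:
    """Centered moving variance (mean-removed mean square) per sample.

    Using variance rather than raw mean-square keeps the gravity offset
    on an acceleration channel from saturating the detector.
    """
    mean = moving_average(signal, window_len).values
    mean_sq = moving_average(signal.with_values(signal.values**2), window_len).values
    return np.maximum(mean_sq - mean**2, 0.0)


def detect_activity(
    accel_x: UniformSignal,
    window_len: int = 501,
    energy_threshold: float | None = None,
    threshold_frac: float = 0.05,
) -> ActivityMask:
    """Flag samples whose windowed energy exceeds a threshold.

    Parameters
    ----------
    accel_x
        Smoothed, upsampled x-axis acceleration.
    window_len
        Centered energy window in samples (odd).
    energy_threshold
        Absolute variance threshold in signal-units².  When ``None`` the
        threshold adapts to the recording: ``threshold_frac`` times the
        maximum windowed variance, so it is unit-free.
    """
    energy = windowed_variance(accel_x, window_len)
    if energy_threshold is None:
        energy_threshold = threshold_frac * float(energy.max())
    if energy_threshold < 0:
        raise InvalidParameterError("energy_threshold must be >= 0")
    return ActivityMask((energy > energy_threshold).astype(np.int8), accel_x.fs)


def remove_short_bouts(
    mask: ActivityMask, min_len: int = DEFAULT_MIN_BOUT_SAMPLES
) -> ActivityMask:
    """Zero out maximal 1-runs shorter than ``min_len`` samples."""
    if min_len < 1:
        raise InvalidParameterError("min_len must be >= 1")
    values = mask.values.copy()
    for start, end in mask.runs():
        if end - start < min_len:
            values[start:end] = 0
    return ActivityMask(values, mask.fs)


def extract_half_trials(mask: ActivityMask) -> list[HalfTrial]:
    """One half-trial per surviving activity bout, in time order."""
    return [HalfTrial(start, end) for start, end in mask.runs()]


def assign_directions(half_trials: list[HalfTrial]) -> list[HalfTrial]:
    """Alternate forward/reverse from the protocol order.

    The subject walks A->B, rests, then returns B->A, twice per
    recording; direction is an experiment-derived variable, so the first
    bout is forward and directions alternate thereafter.
    """
    if len(half_trials) % 2 != 0:
        log.warning(
            "expected an even number of half-trials, got %d; alternating anyway",
            len(half_trials),
        )
    return [
        replace(ht, direction=FORWARD if i % 2 == 0 else REVERSE)
        for i, ht in enumerate(half_trials)
    ]
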