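"""Walking-modality segmentation from y-axis position.

The course design forces a sharp turn at every modality transition, so
within one half-trial the y-position trace shows two prominent local
extrema.  Those two turns split the half-trial into three contiguous
segments, labeled by walking direction: ramp-descent, level-ground,
stair-ascent going out (RD, LGW, SA) and stair-descent, level-ground,
ramp-ascent coming back (SD, LGW, RA).  A safety margin is then padded
onto each segment before EMG extraction so boundary activity is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .activity import FORWARD, REVERSE, HalfTrial
from .errors import InvalidInputError, InvalidParameterError
from .signal_core import UniformSignal

__all__ = [
    "ModalitySegment",
    "detect_turns",
    "assign_modalities",
    "apply_margin",
    "segment_half_trial",
    "FORWARD_SEQUENCE",
    "REVERSE_SEQUENCE",
]

log = logging.getLogger(__name__)

MODALITY_LABELS = ("RA", "RD", "SA", "SD", "LGW")
FORWARD_SEQUENCE = ("RD", "LGW", "SA")
REVERSE_SEQUENCE = ("SD", "LGW", "RA")

#: Safety margin, samples at 1000 Hz (2 s), padded onto each segment so
#: activity at the transition is not clipped.
DEFAULT_MARGIN_SAMPLES = 2000

#: Turn prominence floor as a fraction of the half-trial's y-range.
DEFAULT_PROMINENCE_FRAC = 0.2


@dataclass(frozen=True)
class ModalitySegment:
    """A labeled [start, end) sample interval within one half-trial.

    ``start``/``end`` are the unpadded transition bounds used for
    reporting; ``padded_start``/``padded_end`` include the safety margin
    and drive EMG extraction.  ``fallback_used`` flags segments produced
    by the equal-thirds fallback when turn detection failed.
    """

    label: str
    start: int
    end: int
    half_trial_id: int
    direction: str
    padded_start: int | None = None
    padded_end: int | None = None
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.label not in MODALITY_LABELS:
            raise InvalidParameterError(f"unknown modality label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(f"bad segment bounds [{self.start}, {self.end})")
        if self.direction not in (FORWARD, REVERSE):
            raise InvalidParameterError(f"bad direction {self.direction!r}")

    @property
    def extraction_bounds(self) -> tuple[int, int]:
        if self.padded_start is None or self.padded_end is None:
            return self.start, self.end
        return self.padded_start, self.padded_end


def _turns_with_prominence(
    position_y: UniformSignal, half_trial: HalfTrial, prominence_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    if not (0 <= half_trial.start < half_trial.end <= len(position_y)):
        raise InvalidInputError("half-trial bounds outside position signal")
    y = position_y.values[half_trial.start : half_trial.end]
    y_range = float(np.ptp(y))
    if y_range == 0.0:
        return np.array([], dtype=int), np.array([])
    floor = prominence_frac * y_range
    peaks_hi, props_hi = find_peaks(y, prominence=floor)
    peaks_lo, props_lo = find_peaks(-y, prominence=floor)
    idx = np.concatenate([peaks_hi, peaks_lo])
    prom = np.concatenate([props_hi["prominences"], props_lo["prominences"]])
    order = np.argsort(idx)
    return idx[order] + half_trial.start, prom[order]


def detect_turns(
    position_y: UniformSignal,
    half_trial: HalfTrial,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> list[int]:
    """Prominent y-position extrema (turns) inside one half-trial.

    A turn is a local maximum or minimum of y-position whose prominence
    exceeds ``prominence_frac`` of the half-trial's y-range.  Returns
    absolute sample indices in time order; the course layout implies
    exactly two.
    """
    idx, _ = _turns_with_prominence(position_y, half_trial, prominence_frac)
    return idx.tolist()


def assign_modalities(
    turns: list[int], half_trial: HalfTrial, half_trial_id: int = 0
) -> list[ModalitySegment]:
    """Split a half-trial at its two turns into three labeled segments.

    Forward half-trials are labeled (RD, LGW, SA) in order, reverse ones
    (SD, LGW, RA); the three segments abut exactly and partition the
    half-trial.
    """
    if len(turns) != 2:
        raise InvalidInputError(f"need exactly 2 turns, got {len(turns)}")
    t1, t2 = sorted(int(t) for t in turns)
    if not (half_trial.start < t1 < t2 < half_trial.end):
        raise InvalidInputError("turns must lie strictly inside the half-trial")
    if half_trial.direction is None:
        raise InvalidInputError("half-trial direction must be set before labeling")
    labels = FORWARD_SEQUENCE if half_trial.direction == FORWARD else REVERSE_SEQUENCE
    bounds = [half_trial.start, t1, t2, half_trial.end]
    return [
        ModalitySegment(
            label=labels[i],
            start=bounds[i],
            end=bounds[i + 1],
            half_trial_id=half_trial_id,
            direction=half_trial.direction,
        )
        for i in range(3)
    ]


def apply_margin(
    segment: ModalitySegment,
    margin: int = DEFAULT_MARGIN_SAMPLES,
    signal_len: int | None = None,
) -> ModalitySegment:
    """Pad a segment by ``margin`` samples each side, clipped to bounds.

    Margins serve inclusion, not partitioning: padded neighbours may
    overlap, and the unpadded bounds are retained for reporting.
    """
    if margin < 0:
        raise InvalidParameterError("margin must be >= 0")
    if signal_len is None:
        raise InvalidParameterError("signal_len is required to clip the margin")
    return replace(
        segment,
        padded_start=max(0, segment.start - margin),
        padded_end=min(signal_len, segment.end + margin),
    )


def segment_half_trial(
    position_y: UniformSignal,
    half_trial: HalfTrial,
    half_trial_id: int = 0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    margin: int = DEFAULT_MARGIN_SAMPLES,
) -> list[ModalitySegment]:
    """Turn detection plus labeling, with an equal-thirds fallback.

    When fewer than two sufficiently prominent turns are found, the
    half-trial is split into equal thirds and every resulting segment is
    flagged ``fallback_used``.  When more than two clear the floor, the
    two most prominent are kept.
    """
    idx, prom = _turns_with_prominence(position_y, half_trial, prominence_frac)
    if len(idx) > 2:
        keep = np.sort(np.argsort(prom)[-2:])
        idx = idx[keep]
    turns = idx.tolist()
    fallback = False
    if len(turns) != 2:
        log.warning(
            "half-trial %d: expected 2 turns, found %d; falling back to equal thirds",
            half_trial_id,
            len(turns),
        )
        third = half_trial.n_samples // 3
        turns = [half_trial.start + third, half_trial.start + 2 * third]
        fallback = True
    segments = assign_modalities(turns, half_trial, half_trial_id)
    segments = [
        replace(apply_margin(seg, margin, len(position_y)), fallback_used=fallback)
        for seg in segments
    ]
    return segments
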