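"""Scoring of detected gait events against ground truth.

Detected and true heel-strike times are paired one-to-one by greedy
nearest-first matching within a tolerance; precision, recall, F1 and
timing-error statistics follow from the matching.  The default tolerance
of ±50 ms corresponds to about three samples of a 60 Hz IMU.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["MatchReport", "match_events", "DEFAULT_TOLERANCE_S"]

DEFAULT_TOLERANCE_S = 0.05


@dataclass(frozen=True)
class MatchReport:
    """Detection and timing metrics from a one-to-one event matching."""

    n_true: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    f1: float
    mean_abs_error_s: float
    max_abs_error_s: float
    tolerance_s: float
    degenerate: bool = False  # a side was empty; zero metrics by convention

    def to_dict(self) -> dict:
        return asdict(self)


def match_events(
    detected: np.ndarray, truth: np.ndarray, tol_s: float = DEFAULT_TOLERANCE_S
) -> MatchReport:
    """Greedy nearest-first one-to-one matching within ``tol_s``.

    Candidate (detected, true) pairs with |Δt| ≤ tol are consumed in
    order of ascending |Δt|; each event participates in at most one
    pair.  Greedy matching coincides with the optimal assignment on
    well-separated event trains and is accepted as-is elsewhere.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not tol_s > 0:
        raise InvalidParameterError("tol_s must be > 0")
    for name, arr in (("detected", detected), ("truth", truth)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise InvalidInputError(f"{name} times must be sorted")

    pairs: list[tuple[float, int, int]] = []
    for i, td in enumerate(detected):
        dt = np.abs(truth - td)
        for j in np.flatnonzero(dt <= tol_s):
            pairs.append((float(dt[j]), i, int(j)))
    pairs.sort()

    used_d: set[int] = set()
    used_t: set[int] = set()
    errors: list[float] = []
    for err, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errors.append(err)

    n_matched = len(errors)
    degenerate = detected.size == 0 or truth.size == 0
    precision = n_matched / detected.size if detected.size else 0.0
    recall = n_matched / truth.size if truth.size else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchReport(
        n_true=int(truth.size),
        n_detected=int(detected.size),
        n_matched=n_matched,
        precision=precision,
        recall=recall,
        f1=f1,
        mean_abs_error_s=float(np.mean(errors)) if errors else 0.0,
        max_abs_error_s=float(np.max(errors)) if errors else 0.0,
        tolerance_s=tol_s,
        degenerate=degenerate,
    )
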