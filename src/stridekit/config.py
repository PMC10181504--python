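"""Run configuration: every tunable of the pipeline in one place.

Sample-count thresholds that are conventionally quoted in samples on the
1000 Hz timeline (the 6000-sample bout floor, the 2000-sample safety
margin) are stored here in seconds so they survive sampling-rate
changes; the pipeline converts back to samples at the working rate.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .heelstrike import CadenceParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # sampling
    fs_imu: float = 60.0
    fs_emg: float = 1000.0
    # kinematic smoothing (seconds; 0.25 s = 15 samples at 60 Hz)
    smoothing_window_s: float = 0.25
    # activity detection
    activity_window_s: float = 0.5
    activity_threshold_frac: float = 0.05
    activity_threshold_abs: float | None = None
    min_bout_s: float = 6.0
    # modality segmentation
    turn_prominence_frac: float = 0.2
    segment_margin_s: float = 2.0
    # EMG conditioning
    emg_band_hz: tuple[float, float] = (10.0, 150.0)
    emg_band_order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 30.0
    # heel-strike envelope cascade
    hs_highpass_hz: float = 9.0
    hs_lowpass_hz: float = 6.0
    hs_filter_order: int = 7
    # peak picking
    expected_cadence_spm: float = 100.0
    cadence_tolerance: float = 0.5
    min_peak_height: float = 0.3
    abs_peak_height: float | None = None
    expected_velocity_mps: float | None = None
    # per-cycle summaries
    n_norm: int = 101
    summary_envelope_hz: float = 6.0
    # evaluation
    match_tolerance_s: float = 0.05

    def __post_init__(self) -> None:
        positive = (
            "fs_imu", "fs_emg", "smoothing_window_s", "activity_window_s",
            "min_bout_s", "notch_hz", "notch_q", "hs_highpass_hz",
            "hs_lowpass_hz", "expected_cadence_spm", "summary_envelope_hz",
            "match_tolerance_s",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0 < self.activity_threshold_frac <= 1:
            raise InvalidParameterError("activity_threshold_frac must be in (0, 1]")
        if not 0 < self.turn_prominence_frac < 1:
            raise InvalidParameterError("turn_prominence_frac must be in (0, 1)")
        if self.segment_margin_s < 0:
            raise InvalidParameterError("segment_margin_s must be >= 0")
        lo, hi = self.emg_band_hz
        if not 0 < lo < hi:
            raise InvalidParameterError("emg_band_hz must be two increasing positives")
        if self.emg_band_order < 1 or self.hs_filter_order < 1:
            raise InvalidParameterError("filter orders must be >= 1")
        if not 0 < self.cadence_tolerance < 1:
            raise InvalidParameterError("cadence_tolerance must be in (0, 1)")
        if not 0 < self.min_peak_height <= 1:
            raise InvalidParameterError("min_peak_height must be in (0, 1]")
        if self.n_norm < 2:
            raise InvalidParameterError("n_norm must be >= 2")
        object.__setattr__(self, "emg_band_hz", tuple(float(c) for c in self.emg_band_hz))

    # --- derived sample counts on the working (EMG) timeline ---
    @property
    def smoothing_window_samples(self) -> int:
        return _odd(round(self.smoothing_window_s * self.fs_imu))

    @property
    def activity_window_samples(self) -> int:
        return _odd(round(self.activity_window_s * self.fs_emg))

    @property
    def min_bout_samples(self) -> int:
        return int(round(self.min_bout_s * self.fs_emg))

    @property
    def segment_margin_samples(self) -> int:
        return int(round(self.segment_margin_s * self.fs_emg))

    def cadence_params(self) -> CadenceParams:
        return CadenceParams(
            expected_cadence_spm=self.expected_cadence_spm,
            cadence_tolerance=self.cadence_tolerance,
            min_peak_height=self.min_peak_height,
            abs_peak_height=self.abs_peak_height,
            expected_velocity_mps=self.expected_velocity_mps,
        )

    # --- serialization ---
    def to_dict(self) -> dict:
        d = asdict(self)
        d["emg_band_hz"] = list(self.emg_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "emg_band_hz" in d:
            d = {**d, "emg_band_hz": tuple(d["emg_band_hz"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _odd(n: int) -> int:
    """Nearest odd window length >= 1 (centered windows need odd sizes)."""
    n = max(1, int(n))
    return n if n % 2 == 1 else n + 1
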