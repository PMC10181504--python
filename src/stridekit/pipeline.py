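"""End-to-end pipeline: IMU preprocessing through per-cycle EMG summaries.

Stages, in order: smooth and upsample the kinematics onto the EMG
timeline; threshold windowed energy into a walking mask and reject short
bouts; extract half-trials and assign protocol directions; split each
half-trial into three modality segments at the y-position turns; condition
the EMG; detect heel strikes per segment from the z-acceleration envelope;
build gait cycles and cut, time-normalize and summarize the EMG per cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import activity as act
from . import emg as emg_mod
from . import heelstrike as hs
from . import modality as mod
from .config import PipelineConfig
from .emg import CycleMatrix, EmgRecording
from .signal_core import UniformSignal, moving_average, upsample_linear

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    config: PipelineConfig
    mask: act.ActivityMask
    half_trials: list[act.HalfTrial]
    segments: list[mod.ModalitySegment]
    events: list[hs.GaitEventSeries]          # parallel to segments
    cycles: list[list[hs.GaitCycle]]          # parallel to segments
    matrices: list[CycleMatrix | None]        # parallel to segments
    summaries: pd.DataFrame | None
    upsampled: dict[str, UniformSignal] = field(default_factory=dict)
    emg_conditioned: EmgRecording | None = None

    @property
    def fs(self) -> float:
        return self.mask.fs

    @property
    def n_events(self) -> int:
        return sum(len(e) for e in self.events)

    def event_rows(self) -> list[dict]:
        rows = []
        for seg, series in zip(self.segments, self.events):
            for k, t in enumerate(series.times_s):
                rows.append(
                    {
                        "event_index": k,
                        "time_s": float(t),
                        "segment_label": seg.label,
                        "half_trial": seg.half_trial_id,
                        "direction": seg.direction,
                    }
                )
        return rows


def _upsample_imu(
    imu: dict[str, UniformSignal], config: PipelineConfig, target_n: int
) -> dict[str, UniformSignal]:
    smoothed_x = moving_average(imu["accel_x"], config.smoothing_window_samples)
    out = {
        "accel_x": upsample_linear(smoothed_x, target_n),
        "accel_z": upsample_linear(imu["accel_z"], target_n),
        "pos_y": upsample_linear(imu["pos_y"], target_n),
    }
    if "accel_y" in imu:
        out["accel_y"] = upsample_linear(imu["accel_y"], target_n)
    return out


def run_pipeline(
    imu: dict[str, UniformSignal],
    emg: EmgRecording | None = None,
    config: PipelineConfig | None = None,
    summary_rectified_envelope: bool = False,
) -> PipelineResult:
    """Run every stage on one recording.

    ``emg`` may be ``None`` for kinematics-only datasets; heel-strike
    events are still produced and the EMG stages are skipped.  A
    recording of pure rest yields zero half-trials and empty downstream
    results, not an error.
    """
    config = config or PipelineConfig()
    if emg is not None:
        target_n = emg.n_samples
    else:
        target_n = int(round(imu["accel_x"].duration * config.fs_emg)) + 1

    up = _upsample_imu(imu, config, target_n)
    fs = up["accel_x"].fs

    # walking mask, bout filtering, half-trials
    mask = act.detect_activity(
        up["accel_x"],
        window_len=config.activity_window_samples,
        energy_threshold=config.activity_threshold_abs,
        threshold_frac=config.activity_threshold_frac,
    )
    mask = act.remove_short_bouts(mask, config.min_bout_samples)
    half_trials = act.assign_directions(act.extract_half_trials(mask))
    log.info("detected %d half-trials", len(half_trials))

    # modality segmentation per half-trial
    segments: list[mod.ModalitySegment] = []
    for ht_id, ht in enumerate(half_trials):
        segments.extend(
            mod.segment_half_trial(
                up["pos_y"],
                ht,
                half_trial_id=ht_id,
                prominence_frac=config.turn_prominence_frac,
                margin=config.segment_margin_samples,
            )
        )

    # EMG conditioning
    emg_cond = None
    if emg is not None:
        emg_cond = emg_mod.preprocess_emg(
            emg,
            bandpass_hz=config.emg_band_hz,
            bandpass_order=config.emg_band_order,
            notch_hz=config.notch_hz,
            notch_q=config.notch_q,
        )

    # heel strikes per modality segment (envelope computed once globally,
    # peak threshold adapted per segment)
    envelope = hs.hs_envelope(
        up["accel_z"],
        hp_cutoff_hz=config.hs_highpass_hz,
        lp_cutoff_hz=config.hs_lowpass_hz,
        order=config.hs_filter_order,
    )
    cadence = config.cadence_params()
    events: list[hs.GaitEventSeries] = []
    cycles: list[list[hs.GaitCycle]] = []
    matrices: list[CycleMatrix | None] = []
    summary_frames: list[pd.DataFrame] = []
    for seg in segments:
        env_seg = envelope.crop(seg.start, seg.end)
        series = hs.detect_heel_strikes(env_seg, cadence, label=seg.label)
        seg_cycles = hs.build_gait_cycles(series)
        events.append(series)
        cycles.append(seg_cycles)
        if emg_cond is None or len(seg_cycles) == 0:
            matrices.append(None)
            continue
        crops = emg_mod.segment_by_cycles(emg_cond, seg_cycles)
        matrix = emg_mod.time_normalize(crops, seg_cycles, n_norm=config.n_norm)
        matrices.append(matrix)
        if matrix.cycles:
            summary = emg_mod.summarize_cycles(
                matrix,
                rectified_envelope=summary_rectified_envelope,
                envelope_cutoff_hz=config.summary_envelope_hz,
            )
            summary.insert(0, "half_trial", seg.half_trial_id)
            summary.insert(1, "segment_label", seg.label)
            summary_frames.append(summary)

    summaries = (
        pd.concat(summary_frames, ignore_index=True) if summary_frames else None
    )
    return PipelineResult(
        config=config,
        mask=mask,
        half_trials=half_trials,
        segments=segments,
        events=events,
        cycles=cycles,
        matrices=matrices,
        summaries=summaries,
        upsampled=up,
        emg_conditioned=emg_cond,
    )
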