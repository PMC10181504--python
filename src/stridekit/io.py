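"""Readers and writers for the delimited recording format and results.

A recording lives in a directory:

* ``imu.csv``  — header ``accel_x,accel_y,accel_z,pos_y``; one row per
  60 Hz sample (acceleration in m/s², position in m).
* ``emg.csv``  — header with muscle names (``TA,mGAST,VL,RF,SEM,BFL``);
  one row per 1000 Hz sample, µV.
* ``meta.yaml`` — sampling rates (``fs_imu``, ``fs_emg``) and optional
  subject/trial identifiers.
* ``ground_truth.json`` — present for simulated recordings only.

Result writers emit events as CSV, modality segments as JSON records,
cycle matrices as one CSV per muscle, and evaluation reports as JSON —
all plain text, all re-readable by this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .emg import MUSCLES, CycleMatrix, EmgRecording
from .errors import InvalidInputError
from .modality import ModalitySegment
from .signal_core import UniformSignal
from .synthetic import GroundTruth

__all__ = [
    "read_recording",
    "write_recording",
    "read_ground_truth",
    "write_events_csv",
    "read_events_csv",
    "write_segments_json",
    "write_cycle_matrix_csv",
    "write_report_json",
]

log = logging.getLogger(__name__)

IMU_CHANNELS = ("accel_x", "accel_y", "accel_z", "pos_y")


def read_recording(
    path: str | Path, config: PipelineConfig | None = None
) -> tuple[dict[str, UniformSignal], EmgRecording | None]:
    """Load a recording directory into typed, validated signals.

    Sampling rates come from ``meta.yaml`` when present and must agree
    with the config if both are given.  A missing required IMU channel
    is an error naming the channel; unknown extra columns are accepted
    with a warning and ignored.  ``emg.csv`` is optional (kinematics-only
    datasets).
    """
    path = Path(path)
    config = config or PipelineConfig()
    meta_path = path / "meta.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    fs_imu = float(meta.get("fs_imu", config.fs_imu))
    fs_emg = float(meta.get("fs_emg", config.fs_emg))
    for name, meta_fs, cfg_fs in (("fs_imu", fs_imu, config.fs_imu),
                                  ("fs_emg", fs_emg, config.fs_emg)):
        if name in meta and not np.isclose(meta_fs, cfg_fs):
            raise InvalidInputError(
                f"{name} mismatch: meta.yaml says {meta_fs}, config says {cfg_fs}"
            )

    imu_df = pd.read_csv(path / "imu.csv")
    missing = [c for c in IMU_CHANNELS if c not in imu_df.columns]
    if missing:
        raise InvalidInputError(f"imu.csv missing required channel(s): {missing}")
    extra = [c for c in imu_df.columns if c not in IMU_CHANNELS]
    if extra:
        log.warning("ignoring unknown IMU channel(s): %s", extra)
    imu = {
        name: UniformSignal(imu_df[name].to_numpy(), fs_imu, name)
        for name in IMU_CHANNELS
    }

    emg = None
    emg_path = path / "emg.csv"
    if emg_path.exists():
        emg_df = pd.read_csv(emg_path)
        known = [c for c in emg_df.columns if c in MUSCLES]
        unknown = [c for c in emg_df.columns if c not in MUSCLES]
        if unknown:
            log.warning("ignoring unknown EMG channel(s): %s", unknown)
        if not known:
            raise InvalidInputError(
                f"emg.csv has no recognized muscle columns (expected among {MUSCLES})"
            )
        emg = EmgRecording(
            {m: UniformSignal(emg_df[m].to_numpy(), fs_emg, m) for m in known},
            subject=str(meta.get("subject", "")),
            trial=str(meta.get("trial", "")),
        )
    return imu, emg


def write_recording(
    path: str | Path,
    imu: dict[str, UniformSignal],
    emg: EmgRecording | None = None,
    truth: GroundTruth | None = None,
    float_fmt: str = "%.6g",
) -> Path:
    """Write a recording directory in the format ``read_recording`` reads."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    imu_df = pd.DataFrame({name: sig.values for name, sig in imu.items()})
    imu_df.to_csv(path / "imu.csv", index=False, float_format=float_fmt)
    meta = {"fs_imu": float(next(iter(imu.values())).fs)}
    if emg is not None:
        emg_df = pd.DataFrame(
            {m: emg.channels[m].values for m in emg.muscles}
        )
        emg_df.to_csv(path / "emg.csv", index=False, float_format=float_fmt)
        meta.update(fs_emg=float(emg.fs), subject=emg.subject, trial=emg.trial)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    if path.is_dir():
        path = path / "ground_truth.json"
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def write_events_csv(path: str | Path, rows: list[dict]) -> Path:
    """Events table: event_index, time_s, segment_label, half_trial, direction."""
    path = Path(path)
    cols = ["event_index", "time_s", "segment_label", "half_trial", "direction"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["half_trial", "time_s"], kind="stable").reset_index(drop=True)
    df["event_index"] = np.arange(len(df))
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_segments_json(path: str | Path, segments: list[ModalitySegment], fs: float) -> Path:
    """Modality segments as JSON records with seconds-valued bounds."""
    records = []
    for seg in segments:
        pad_start, pad_end = seg.extraction_bounds
        records.append(
            {
                "half_trial": seg.half_trial_id,
                "direction": seg.direction,
                "label": seg.label,
                "start_s": seg.start / fs,
                "end_s": seg.end / fs,
                "padded_start_s": pad_start / fs,
                "padded_end_s": pad_end / fs,
                "fallback_used": seg.fallback_used,
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
    return path


def write_cycle_matrix_csv(directory: str | Path, matrix: CycleMatrix, prefix: str = "") -> list[Path]:
    """One CSV per muscle: rows = cycles, columns = normalized phase."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for muscle in matrix.data:
        out = directory / f"{prefix}{muscle}_cycles.csv"
        matrix.to_frame(muscle).to_csv(out, index_label="cycle", float_format="%.6g")
        written.append(out)
    return written


def write_report_json(path: str | Path, report: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonify)
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
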