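"""Plain-text readers and writers for the pipeline's on-disk formats.

sEMG and IMU streams travel as CSV (``time_s`` plus one column per channel),
trial logs as JSON Lines, course manifests and preprocessing reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from aanrehab.streams import SignalStream
from aanrehab.synth import SyntheticCourse, TrialSpec


def write_stream_csv(stream: SignalStream, path) -> None:
    stream.to_frame().to_csv(path, index=False)


def read_emg_csv(path, fs: float = 1000.0) -> SignalStream:
    return SignalStream.from_frame(pd.read_csv(path), fs=fs, modality="emg")


def read_imu_csv(path, fs: float = 100.0) -> tuple[SignalStream, SignalStream]:
    """Read a combined IMU CSV into (gyro, accel) streams."""
    frame = pd.read_csv(path)
    gyro_cols = [c for c in frame.columns if c.startswith("gyro")]
    accel_cols = [c for c in frame.columns if c.startswith("accel")]
    gyro = SignalStream(frame[gyro_cols].to_numpy().T, fs=fs,
                        modality="imu_gyro", channel_names=gyro_cols)
    accel = SignalStream(frame[accel_cols].to_numpy().T, fs=fs,
                         modality="imu_accel", channel_names=accel_cols)
    return gyro, accel


def write_imu_csv(gyro: SignalStream, accel: SignalStream, path) -> None:
    frame = gyro.to_frame()
    for name in accel.channel_names:
        frame[name] = accel.channel(name)
    frame.to_csv(path, index=False)


def write_trials_jsonl(trials: list[TrialSpec], path) -> None:
    with open(path, "w") as fh:
        for tr in trials:
            fh.write(json.dumps(
                {
                    "trial_id": tr.trial_id,
                    "t_start_s": tr.t_start,
                    "t_end_s": tr.t_end,
                    "D_cm": tr.distance_D,
                    "W_cm": tr.width_W,
                    "success": tr.success,
                    "completion_time_s": tr.duration_T,
                }
            ) + "\n")


def read_trials_jsonl(path) -> list[TrialSpec]:
    trials = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            trials.append(
                TrialSpec(
                    trial_id=rec["trial_id"],
                    distance_D=rec["D_cm"],
                    width_W=rec["W_cm"],
                    duration_T=rec["completion_time_s"],
                    t_start=rec["t_start_s"],
                    t_end=rec["t_end_s"],
                    success=rec["success"],
                )
            )
    return trials


def write_course(course: SyntheticCourse, out_dir) -> Path:
    """Write a synthetic course to a directory of CSV/JSONL files + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": course.patient.subject_id,
        "n_sessions": course.config.n_sessions,
        "trials_per_session": course.config.trials_per_session,
        "seed": course.config.seed,
        "anchors": {
            "fma_0": course.anchors.fma_0,
            "fma_t": course.anchors.fma_t,
            "arat_0": course.anchors.arat_0,
            "arat_t": course.anchors.arat_t,
        },
        "sessions": [],
    }
    for bundle in course.sessions:
        tag = f"s{bundle.session:02d}"
        write_stream_csv(bundle.emg, out / f"{tag}_emg.csv")
        write_imu_csv(bundle.gyro, bundle.accel, out / f"{tag}_imu.csv")
        write_trials_jsonl(bundle.trials, out / f"{tag}_trials.jsonl")
        manifest["sessions"].append(
            {
                "session": bundle.session,
                "capability": bundle.capability,
                "assist": bundle.assist,
                "difficulty": bundle.difficulty,
                "emg": f"{tag}_emg.csv",
                "imu": f"{tag}_imu.csv",
                "trials": f"{tag}_trials.jsonl",
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"
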