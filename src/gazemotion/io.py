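"""Readers and writers for the pipeline's on-disk artifacts.

Gaze streams are TSV (one file per participant x movie) with columns
``timestamp_s  x_px  y_px  pupil_left  pupil_right  valid``; movie labels a
two-column CSV; luminance series CSV; feature tables CSV; ground truth and
evaluation results JSON.  Frames are written as 8-bit grayscale PNG
sequences (lossy quantization of the float frames, for inspection only).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .luminance import LuminanceSeries
from .recording import GazeRecording
from .synth import Cohort, GroundTruth

GAZE_COLUMNS = ["timestamp_s", "x_px", "y_px", "pupil_left", "pupil_right", "valid"]


def write_gaze_tsv(recording: GazeRecording, path) -> None:
    df = pd.DataFrame({
        "timestamp_s": recording.timestamps,
        "x_px": recording.gaze_x,
        "y_px": recording.gaze_y,
        "pupil_left": recording.pupil_left,
        "pupil_right": recording.pupil_right,
        "valid": recording.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gaze_tsv(path, participant_id: str = "", movie_id: str = "") -> GazeRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["timestamp_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    rate = 1.0 / np.median(np.diff(t))
    if not participant_id or not movie_id:
        # conventional file name: <participant>_<movie>.tsv
        stem = path.stem
        parts = stem.split("_", 1)
        participant_id = participant_id or parts[0]
        movie_id = movie_id or (parts[1] if len(parts) > 1 else stem)
    return GazeRecording(
        participant_id, movie_id, round(rate, 6),
        np.arange(len(t)) / round(rate, 6),
        df["x_px"].to_numpy(float), df["y_px"].to_numpy(float),
        df["pupil_left"].to_numpy(float), df["pupil_right"].to_numpy(float),
        df["valid"].to_numpy().astype(bool),
    )


def write_labels_csv(labels: dict, path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["movie_id", "class"]).to_csv(path, index=False)


def read_labels_csv(path) -> dict:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["movie_id"], df["class"]))


def write_luminance_csv(series: LuminanceSeries, path) -> None:
    pd.DataFrame({"frame": np.arange(series.n_frames), "luminance": series.values}).to_csv(
        path, index=False, float_format="%.8f"
    )


def read_luminance_csv(path, frame_rate: float, movie_id: str = "") -> LuminanceSeries:
    df = pd.read_csv(path)
    return LuminanceSeries(df["luminance"].to_numpy(float), frame_rate, movie_id)


def _truth_to_jsonable(t: GroundTruth) -> dict:
    d = dataclasses.asdict(t)
    d["aligned_luminance"] = np.asarray(t.aligned_luminance).tolist()
    d["emotion_signal"] = np.asarray(t.emotion_signal).tolist()
    return d


def write_ground_truth_json(cohort: Cohort, path) -> None:
    payload = {
        f"{pid}:{mid}": _truth_to_jsonable(t)
        for (pid, mid), t in sorted(cohort.ground_truth.items())
    }
    Path(path).write_text(json.dumps(payload))


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format="%.10g")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str, "movie_id": str, "class_label": str})


def write_frames_png(frames: np.ndarray, directory, prefix: str = "frame") -> list[Path]:
    """Dump a float [0, 1] frame stack as an 8-bit grayscale PNG sequence."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    data = np.clip(np.asarray(frames), 0.0, 1.0)
    for i, frame in enumerate(data):
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, (frame * 255).round().astype(np.uint8))
        paths.append(p)
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results_json(result, path) -> None:
    """Serialize the headline outputs of a :class:`~gazemotion.pipeline.StudyResult`."""
    payload = {
        "rejected_participants": list(result.rejection.rejected),
        "loss_by_participant": _jsonable(result.rejection.loss_by_participant),
        "accuracy_table": _jsonable(result.accuracy_table),
        "confusion_matrices": {
            f"{task}/{model}": _jsonable(r.confusion.to_frame())
            for (task, model), r in result.loso.items()
        },
        "metrics": {
            f"{task}/{model}": _jsonable(r.metrics.to_frame())
            for (task, model), r in result.loso.items()
        },
        "fold_accuracies": {
            f"{task}/{model}": _jsonable(r.fold_accuracies)
            for (task, model), r in result.loso.items()
        },
        "luminance_models": {
            pid: {"b0": m.b0, "b1": m.b1} for pid, m in result.luminance_models.items()
        },
    }
    if result.dynamics is not None:
        payload["dynamics_index"] = _jsonable(result.dynamics)
        payload["dynamics_correlations"] = _jsonable(result.dynamics_correlations)
    if result.luminance_diagnostics is not None:
        payload["luminance_diagnostics"] = _jsonable(result.luminance_diagnostics)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
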