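"""Readers and writers for the package's plain-text formats.

Recordings are CSV files with columns ``time_s,amplitude``; a directory
of recordings carries a ``manifest.csv`` mapping files to subject,
trial and label.  Feature tables, model JSON and report JSON round-trip
through pandas/json.  All writers go through a temp-file-then-rename so
a failed write never leaves a partial file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .synth import EMGRecording, LabeledDataset
from .tsvm import MulticlassTSVM

__all__ = [
    "atomic_write_text",
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

MANIFEST_NAME = "manifest.csv"


def atomic_write_text(path, text: str) -> None:
    """Write text via a temporary file and rename; never leaves partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_recording(recording: EMGRecording, path) -> None:
    t = np.arange(len(recording.samples)) / recording.fs
    df = pd.DataFrame({"time_s": t, "amplitude": recording.samples})
    atomic_write_text(path, df.to_csv(index=False, float_format="%.12g"))


def read_recording(path, label: str | None = None, trial_id: int = 0,
                   subject_id: str = "S1") -> EMGRecording:
    """Read a ``time_s,amplitude`` CSV; sampling rate from the median Δt.

    Rejects empty files, NaN amplitudes (reporting the first bad row) and
    non-uniform sampling (relative jitter above 1e-6).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: recording file is empty")
    amp = df["amplitude"].to_numpy(dtype=float)
    if np.any(~np.isfinite(amp)):
        row = int(np.flatnonzero(~np.isfinite(amp))[0])
        raise ValueError(f"{path}: non-finite amplitude at data row {row + 1}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(f"{path}: time not strictly increasing at data row {row + 2}")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) > 1e-6 * max(med, 1e-30):
            raise ValueError(f"{path}: non-uniform sampling (jitter above 1e-6 relative)")
        fs = 1.0 / med
    else:
        fs = 1.0
    return EMGRecording(samples=amp, fs=fs, label=label or "background",
                        trial_id=trial_id, subject_id=subject_id)


def write_dataset(dataset: LabeledDataset, out_dir) -> Path:
    """One CSV per recording plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(dataset.recordings):
        name = f"{rec.subject_id}_{rec.label}_t{rec.trial_id:03d}.csv"
        write_recording(rec, out_dir / name)
        rows.append({"file": name, "subject_id": rec.subject_id,
                     "trial_id": rec.trial_id, "label": rec.label})
    manifest = pd.DataFrame(rows)
    path = out_dir / MANIFEST_NAME
    atomic_write_text(path, manifest.to_csv(index=False))
    return path


def read_dataset(data_dir) -> LabeledDataset:
    data_dir = Path(data_dir)
    manifest_path = data_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {data_dir}")
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for _, row in manifest.iterrows():
        recordings.append(read_recording(
            data_dir / row["file"], label=str(row["label"]),
            trial_id=int(row["trial_id"]), subject_id=str(row["subject_id"])))
    class_names = sorted({r.label for r in recordings if r.label != "background"})
    return LabeledDataset(recordings=recordings, class_names=class_names, seed=-1)


def write_feature_table(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("label", *FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return df


def save_model(model: MulticlassTSVM, path) -> None:
    atomic_write_text(path, model.to_json(indent=2))


def load_model(path) -> MulticlassTSVM:
    return MulticlassTSVM.from_json(Path(path).read_text())
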