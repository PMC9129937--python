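"""Delimited-text signal I/O, manifests, feature-matrix and report files.

Recordings travel as plain text: one column per channel, one row per
sample, with comment headers carrying the sampling rate and channel
names (``# fs=250``).  A dataset is a directory of such files plus a
``manifest.csv`` with columns ``recording_id,path,label``.

Feature matrices are CSV with a JSON sidecar holding the group/domain
tags and any fitted standardization parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .preprocess import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_metrics",
]


def write_recording(path, recording: Recording) -> None:
    """One column per channel; header comments carry fs/label/channels."""
    path = Path(path)
    header = (
        f"fs={recording.fs:g}\n"
        f"label={recording.label}\n"
        f"channels={','.join(recording.channel_names)}"
    )
    np.savetxt(path, recording.samples.T, fmt="%.8g", header=header)


def read_recording(path, fs: float | None = None, label: str | None = None) -> Recording:
    """Read a delimited-text recording; header values yield to arguments."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, value = text.split("=", 1)
                meta[key.strip()] = value.strip()
    samples = np.loadtxt(path)
    if samples.ndim == 1:
        samples = samples[:, None]
    channels = meta.get("channels", "").split(",") if meta.get("channels") else []
    return Recording(
        samples=samples.T,
        fs=fs if fs is not None else float(meta.get("fs", 250.0)),
        label=label if label is not None else meta.get("label", "unknown"),
        channel_names=channels or [],
        recording_id=path.stem,
    )


def write_dataset(directory, recordings: list[Recording]) -> Path:
    """Write recordings plus a ``manifest.csv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"{rec.recording_id or 'recording'}.txt"
        write_recording(directory / name, rec)
        rows.append({"recording_id": rec.recording_id, "path": name, "label": rec.label})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path) -> list[Recording]:
    """Load all recordings listed in a manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    recordings = []
    for _, row in table.iterrows():
        rec = read_recording(base / row["path"], label=row["label"])
        rec.recording_id = str(row["recording_id"])
        recordings.append(rec)
    return recordings


def write_feature_matrix(path, fm: FeatureMatrix) -> None:
    """CSV of values plus a ``.json`` sidecar of tags and z-score state."""
    path = Path(path)
    df = fm.values.copy()
    if fm.labels is not None:
        df.insert(0, "__label__", np.asarray(fm.labels))
    if fm.recording_ids is not None:
        df.insert(0, "__recording__", np.asarray(fm.recording_ids))
    df.to_csv(path, index=True)
    sidecar = {
        "groups": fm.groups,
        "domains": fm.domains,
        "standardization": fm.standardization,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    labels = None
    rec_ids = None
    if "__label__" in df.columns:
        labels = df.pop("__label__")
    if "__recording__" in df.columns:
        rec_ids = df.pop("__recording__")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    std = sidecar.get("standardization")
    if std is not None:
        std = {k: tuple(v) for k, v in std.items()}
    return FeatureMatrix(
        values=df,
        groups=sidecar["groups"],
        domains=sidecar["domains"],
        standardization=std,
        labels=labels,
        recording_ids=rec_ids,
    )


def write_metrics(directory, report) -> None:
    """Metrics JSON, per-fold CSV and ROC points CSV for one report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"model{report.variant_id}" if report.variant_id else "model"
    with open(directory / f"{stem}_metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    pd.DataFrame(
        {"fold": range(len(report.fold_accuracies)), "accuracy": report.fold_accuracies}
    ).to_csv(directory / f"{stem}_folds.csv", index=False)
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        directory / f"{stem}_roc.csv", index=False
    )
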