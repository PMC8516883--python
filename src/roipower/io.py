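"""Readers and writers: ASCII/CSV recordings, EDF input, result tables.

Recordings travel as plain text matrices (channels × samples, µV) with a
small comment header carrying the sampling rate and channel labels — the
same shape the original ASCII exports of clinical EEG systems use.  EDF
files are read through mne.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import Recording, default_channel_labels

_FS_KEY = "fs_hz="
_CH_KEY = "channels="


def write_recording_ascii(rec: Recording, path: str | Path,
                          fmt: str = "%.6g") -> None:
    """Plain-text channels × samples matrix with `# fs_hz=` / `# channels=` header."""
    header = f"{_FS_KEY}{rec.fs_hz:g}\n{_CH_KEY}{','.join(rec.channel_labels)}"
    np.savetxt(path, rec.data, fmt=fmt, delimiter=",", header=header)


def read_recording_ascii(path: str | Path, fs_hz: float | None = None,
                         channel_labels: Sequence[str] | None = None) -> Recording:
    """Read a channels × samples ASCII/CSV matrix.

    Header comments win over the `fs_hz` / `channel_labels` arguments; if
    the file has no header, `fs_hz` is required.  A sidecar
    ``<stem>.labels.txt`` (one label per line) is honoured when present.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if text.startswith(_FS_KEY):
                fs_hz = float(text[len(_FS_KEY):])
            elif text.startswith(_CH_KEY):
                channel_labels = text[len(_CH_KEY):].split(",")
    if fs_hz is None:
        raise ValueError(f"{path}: sampling rate not in header and not given")
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    sidecar = path.with_suffix(".labels.txt")
    if channel_labels is None and sidecar.exists():
        channel_labels = [ln.strip() for ln in sidecar.read_text().splitlines()
                          if ln.strip()]
    labels = tuple(channel_labels) if channel_labels \
        else default_channel_labels(data.shape[0])
    return Recording(data=data, fs_hz=fs_hz, channel_labels=labels)


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF recording (converted to µV)."""
    import mne  # deferred: only EDF input needs it

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(data=raw.get_data() * 1e6, fs_hz=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names))


def read_recording(path: str | Path, fs_hz: float | None = None) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    return read_recording_ascii(path, fs_hz=fs_hz)


def write_cohort(recordings: Sequence[Recording], metadata: pd.DataFrame,
                 out_dir: str | Path) -> list[Path]:
    """One ASCII file per subject plus ``metadata.csv``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(recordings) != len(metadata):
        raise ValueError("recordings and metadata rows must align")
    paths = []
    for rec, sid in zip(recordings, metadata["subject_id"]):
        p = out / f"{sid}.csv"
        write_recording_ascii(rec, p)
        paths.append(p)
    metadata.to_csv(out / "metadata.csv", index=False)
    return paths


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "subject_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must have subject_id and group columns")
    return meta
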