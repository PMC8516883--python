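"""Sensor-space preprocessing: raw multi-channel EEG → artifact-free 5 s epochs.

The chain follows the usual resting-state protocol, in this order:

(i) per-channel mean removal; (ii) 50 Hz notch; (iii) 1–70 Hz Hamming-window
bandpass, zero phase; (iv) an optional artifact-removal hook (where an ICA
step would sit — selection of components is rater-dependent, so the default
is the identity); (v) segmentation into non-overlapping 5 s epochs;
(vi) deterministic amplitude/variance epoch rejection replacing visual
rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .filters import fir_bandpass, iir_notch, zero_phase_fir
from scipy import signal as _sig

#: electrode names of the 19-channel 10–20 montage used for default labels
TEN_TWENTY_19 = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4",
                 "Cz", "T3", "T4", "T5", "T6", "P3", "P4", "Pz", "O1", "O2")


def default_channel_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels == len(TEN_TWENTY_19):
        return TEN_TWENTY_19
    return tuple(f"EEG{i + 1:03d}" for i in range(n_channels))


@dataclass(frozen=True)
class Recording:
    """Sensor-space EEG: `data` is [n_channels × n_samples] in µV."""

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D [n_channels × n_samples]")
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        labels = tuple(self.channel_labels) or default_channel_labels(data.shape[0])
        if len(labels) != data.shape[0]:
            raise ValueError("channel_labels length does not match data")
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length segments: `epochs` is [n_epochs × n_channels × n_samples]."""

    epochs: np.ndarray
    fs_hz: float
    epoch_length_s: float
    kept_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self):
        epochs = np.asarray(self.epochs, dtype=float)
        if epochs.ndim != 3:
            raise ValueError("epochs must be 3-D")
        expected = int(round(self.epoch_length_s * self.fs_hz))
        if epochs.shape[0] and epochs.shape[2] != expected:
            raise ValueError("epoch sample count inconsistent with epoch_length_s")
        kept = self.kept_indices
        kept = np.arange(epochs.shape[0]) if kept is None else np.asarray(kept, int)
        if len(kept) != epochs.shape[0]:
            raise ValueError("kept_indices length mismatch")
        if np.any(np.diff(kept) <= 0):
            raise ValueError("kept_indices must be strictly increasing")
        object.__setattr__(self, "epochs", epochs)
        object.__setattr__(self, "kept_indices", kept)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def remove_mean(rec: Recording) -> Recording:
    """Subtract each channel's sample mean (step i)."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    return rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))


def notch_filter(rec: Recording, f0_hz: float = 50.0,
                 quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch at `f0_hz` (step ii)."""
    b, a = iir_notch(f0_hz, rec.fs_hz, quality)
    out = _sig.filtfilt(b, a, rec.data, axis=-1)
    return rec.with_data(out)


def bandpass_filter(rec: Recording, lo_hz: float = 1.0,
                    hi_hz: float = 70.0) -> Recording:
    """Zero-phase Hamming-window FIR bandpass (step iii)."""
    taps = fir_bandpass(lo_hz, hi_hz, rec.fs_hz)
    return rec.with_data(zero_phase_fir(rec.data, taps))


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean at every sample."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs ≥ 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_epochs(rec: Recording, epoch_length_s: float = 5.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; drop the trailing partial one."""
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    n_per = int(round(epoch_length_s * rec.fs_hz))
    n_epochs = rec.n_samples // n_per
    trimmed = rec.data[:, :n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).swapaxes(0, 1)
    return EpochSet(epochs=epochs.copy(), fs_hz=rec.fs_hz,
                    epoch_length_s=epoch_length_s,
                    kept_indices=np.arange(n_epochs),
                    channel_labels=rec.channel_labels)


def reject_artifact_epochs(epochs: EpochSet,
                           ptp_threshold_uv: float = 150.0,
                           z_threshold: float = 4.0) -> EpochSet:
    """Deterministic stand-in for visual artifact rejection.

    An epoch is dropped when any channel's peak-to-peak amplitude exceeds
    `ptp_threshold_uv`, or when any channel's within-epoch SD exceeds the
    mean + `z_threshold`·SD of that channel's across-epoch SD distribution.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    data = epochs.epochs
    ptp = data.max(axis=2) - data.min(axis=2)              # [n_epochs × n_ch]
    bad_ptp = (ptp > ptp_threshold_uv).any(axis=1)
    sd = data.std(axis=2)                                  # [n_epochs × n_ch]
    mu, sigma = sd.mean(axis=0), sd.std(axis=0)
    with np.errstate(invalid="ignore"):
        bad_var = (sd > mu + z_threshold * sigma).any(axis=1)
    keep = ~(bad_ptp | bad_var)
    if not keep.any():
        warnings.warn("all epochs rejected as artifacts", RuntimeWarning)
    return EpochSet(epochs=data[keep], fs_hz=epochs.fs_hz,
                    epoch_length_s=epochs.epoch_length_s,
                    kept_indices=epochs.kept_indices[keep],
                    channel_labels=epochs.channel_labels)


def preprocess_recording(rec: Recording, *,
                         notch_hz: float = 50.0,
                         band: tuple[float, float] = (1.0, 70.0),
                         epoch_length_s: float = 5.0,
                         ptp_threshold_uv: float = 150.0,
                         z_threshold: float = 4.0,
                         artifact_hook: Callable[[Recording], Recording] | None = None,
                         common_average: bool = True) -> EpochSet:
    """Run the full six-step chain in its canonical order and return epochs.

    `artifact_hook` is the pluggable slot for component-based artifact
    removal (step iv); it receives and must return a `Recording`.
    """
    rec = remove_mean(rec)
    rec = notch_filter(rec, notch_hz)
    rec = bandpass_filter(rec, *band)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    if common_average:
        rec = rereference_common_average(rec)
    epochs = segment_epochs(rec, epoch_length_s)
    if epochs.n_epochs == 0:
        return epochs
    return reject_artifact_epochs(epochs, ptp_threshold_uv, z_threshold)
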