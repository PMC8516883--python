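"""Relative band power from ROI time series.

The per-band statistic is

    RP_b = Σ_{f ∈ band b} PSDn(f),

where PSDn is the power spectral density normalized to unit mass over the
analysis range (1–70 Hz by default).  The PSD is a Welch estimate with 1 s
Hamming segments and 50 % overlap, so frequency bins fall on integer Hz and
the five conventional bands — δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–70 Hz —
tile the analysis range exactly under the half-open convention [lo, hi)
(the top band is closed at 70 Hz).  ΣRP = 1 then holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .inverse import RoiSignals

_EDGE_TOL = 1e-9

DEFAULT_BANDS = (("delta", 1.0, 4.0), ("theta", 4.0, 8.0),
                 ("alpha", 8.0, 13.0), ("beta", 13.0, 30.0),
                 ("gamma", 30.0, 70.0))


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous frequency bands tiling the normalization range."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    f_min: float = 1.0
    f_max: float = 70.0

    def __post_init__(self):
        bands = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.bands)
        if not bands:
            raise ValueError("band scheme is empty")
        if abs(bands[0][1] - self.f_min) > _EDGE_TOL:
            raise ValueError("first band must start at f_min")
        if abs(bands[-1][2] - self.f_max) > _EDGE_TOL:
            raise ValueError("last band must end at f_max")
        for (_, _, hi_prev), (_, lo, _) in zip(bands, bands[1:]):
            if abs(hi_prev - lo) > _EDGE_TOL:
                raise ValueError("bands must be contiguous and non-overlapping")
        for name, lo, hi in bands:
            if lo >= hi:
                raise ValueError(f"band {name!r} has non-positive width")
        object.__setattr__(self, "bands", bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def band_masks(self, frequencies: np.ndarray) -> np.ndarray:
        """Boolean [n_bands × n_freqs] selector; half-open, last band closed."""
        f = np.asarray(frequencies, dtype=float)
        masks = np.zeros((self.n_bands, f.size), dtype=bool)
        for i, (_, lo, hi) in enumerate(self.bands):
            upper = (f <= hi + _EDGE_TOL) if i == self.n_bands - 1 \
                else (f < hi - _EDGE_TOL)
            masks[i] = (f >= lo - _EDGE_TOL) & upper
        return masks


def compute_psd(x: np.ndarray, fs_hz: float, *, method: str = "welch",
                segment_s: float = 1.0, overlap: float = 0.5):
    """PSD of the trailing axis; Welch (1 s Hamming, 50 % overlap) by default.

    Frequency resolution is 1/segment_s (1 Hz).  `method="periodogram"`
    computes a single Hamming periodogram of the whole signal instead.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2 * fs_hz:
        raise ValueError("signal shorter than 2 s; PSD estimate refused")
    if method == "welch":
        nperseg = int(round(segment_s * fs_hz))
        freqs, psd = signal.welch(x, fs=fs_hz, window="hamming",
                                  nperseg=nperseg,
                                  noverlap=int(round(nperseg * overlap)),
                                  axis=-1)
    elif method == "periodogram":
        freqs, psd = signal.periodogram(x, fs=fs_hz, window="hamming", axis=-1)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return freqs, np.maximum(psd, 0.0)


def normalize_psd(frequencies: np.ndarray, psd: np.ndarray,
                  scheme: BandScheme = BandScheme()):
    """Restrict to [f_min, f_max] and scale to unit total mass.

    Returns (frequencies in range, normalized psd); the normalization is
    applied along the trailing axis.
    """
    f = np.asarray(frequencies, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("psd must be nonnegative")
    mask = (f >= scheme.f_min - _EDGE_TOL) & (f <= scheme.f_max + _EDGE_TOL)
    sub = psd[..., mask]
    total = sub.sum(axis=-1, keepdims=True)
    if np.any(total <= 0.0):
        raise ValueError("psd has zero mass in the normalization range")
    return f[mask], sub / total


def relative_power(frequencies: np.ndarray, normalized_psd: np.ndarray,
                   scheme: BandScheme = BandScheme()) -> np.ndarray:
    """Band sums of a unit-mass PSD; output shape (..., n_bands), rows sum to 1."""
    masks = scheme.band_masks(frequencies)
    npsd = np.asarray(normalized_psd, dtype=float)
    return np.stack([npsd[..., m].sum(axis=-1) for m in masks], axis=-1)


def rp_per_subject(roi_signals: "RoiSignals",
                   scheme: BandScheme = BandScheme(), *,
                   method: str = "welch"):
    """Relative power per epoch and ROI, then the across-epoch mean.

    Returns ``(mean_rp, per_epoch_rp)`` with shapes [n_rois × n_bands] and
    [n_epochs × n_rois × n_bands]; the per-epoch array feeds the spatial
    entropy stage.
    """
    data = roi_signals.data
    if data.shape[0] == 0:
        raise ValueError("empty RoiSignals")
    freqs, psd = compute_psd(data, roi_signals.fs_hz, method=method)
    f_in, npsd = normalize_psd(freqs, psd, scheme)
    per_epoch = relative_power(f_in, npsd, scheme)
    return per_epoch.mean(axis=0), per_epoch


def subject_normalized_psd(roi_signals: "RoiSignals",
                           scheme: BandScheme = BandScheme(), *,
                           method: str = "welch"):
    """Subject-level normalized spectrum: per-epoch/ROI PSDn averaged over
    epochs and ROIs (the grand-average-spectrum building block)."""
    freqs, psd = compute_psd(roi_signals.data, roi_signals.fs_hz, method=method)
    f_in, npsd = normalize_psd(freqs, psd, scheme)
    return f_in, npsd.mean(axis=(0, 1))


@dataclass(frozen=True)
class RpTable:
    """Subject × ROI × band relative power; every (subject, ROI) row sums to 1."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    roi_labels: tuple[str, ...]
    band_names: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be [n_subjects × n_rois × n_bands]")
        if v.shape != (len(self.subject_ids), len(self.roi_labels),
                       len(self.band_names)):
            raise ValueError("values shape inconsistent with labels")
        if v.size and (np.any(v < -1e-12)
                       or np.max(np.abs(v.sum(axis=2) - 1.0)) > 1e-9):
            raise ValueError("each (subject, ROI) RP vector must sum to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        object.__setattr__(self, "band_names", tuple(self.band_names))

    def to_long_frame(self) -> pd.DataFrame:
        subs, rois, bands = np.meshgrid(range(len(self.subject_ids)),
                                        range(len(self.roi_labels)),
                                        range(len(self.band_names)),
                                        indexing="ij")
        return pd.DataFrame({
            "subject_id": np.asarray(self.subject_ids)[subs.ravel()],
            "roi": np.asarray(self.roi_labels)[rois.ravel()],
            "band": np.asarray(self.band_names)[bands.ravel()],
            "rp": self.values.ravel(),
        })

    def to_wide_frame(self) -> pd.DataFrame:
        long = self.to_long_frame()
        wide = long.pivot_table(index=["subject_id", "roi"], columns="band",
                                values="rp", sort=False)
        return wide.reset_index()

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "RpTable":
        subjects = tuple(dict.fromkeys(df["subject_id"].astype(str)))
        rois = tuple(dict.fromkeys(df["roi"].astype(str)))
        bands = tuple(dict.fromkeys(df["band"].astype(str)))
        piv = df.set_index(["subject_id", "roi", "band"])["rp"]
        v = np.empty((len(subjects), len(rois), len(bands)))
        for i, s in enumerate(subjects):
            for j, r in enumerate(rois):
                for k, b in enumerate(bands):
                    v[i, j, k] = piv.loc[(s, r, b)]
        return cls(v, subjects, rois, bands)
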