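"""Spatial entropy of the regional distribution of relative power.

SE is the Shannon entropy of the histogram of RP values across cortical
ROIs, normalized by log N so that SE ∈ [0, 1]:

    SE = −(1/log N) Σ_n p_n log p_n,      0·log 0 := 0,

with the bin count set by the Freedman–Diaconis rule
(h = 2·IQR·n^(−1/3)).  A spatially homogeneous power distribution gives a
single occupied bin and SE = 0; equally occupied bins give SE = 1.  The
natural logarithm is used — the ratio is base-invariant.  SE is computed
per epoch on the ROI RP values of one band and then averaged over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def freedman_diaconis_edges(values: np.ndarray) -> np.ndarray:
    """Equal-width histogram edges spanning [min, max] with FD bin width.

    IQR uses linear interpolation of order statistics.  Degenerate inputs
    (IQR = 0 or max = min) collapse to a single bin.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    lo, hi = float(v.min()), float(v.max())
    q1, q3 = np.percentile(v, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    h = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    if h <= 0.0 or hi <= lo:
        return np.array([lo, hi if hi > lo else lo + 1.0])
    n_bins = int(np.ceil((hi - lo) / h))
    return np.linspace(lo, hi, n_bins + 1)


def histogram_probabilities(values: np.ndarray) -> np.ndarray:
    """Normalized FD histogram (last bin right-closed, as np.histogram does)."""
    v = np.asarray(values, dtype=float).ravel()
    edges = freedman_diaconis_edges(v)
    counts, _ = np.histogram(v, bins=edges)
    return counts / counts.sum()


def spatial_entropy(values: np.ndarray) -> float:
    """Normalized Shannon entropy of the FD histogram of `values` ∈ [0, 1]."""
    p = histogram_probabilities(values)
    n_bins = p.size
    if n_bins < 2:
        return 0.0
    nz = p[p > 0.0]
    if nz.size < 2:
        return 0.0
    return float(-(nz * np.log(nz)).sum() / np.log(n_bins))


def se_per_subject(per_epoch_rp: np.ndarray) -> float:
    """Average over epochs of the per-epoch SE of ROI RP values.

    `per_epoch_rp` is [n_epochs × n_rois] for a single band.
    """
    arr = np.asarray(per_epoch_rp, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a nonempty [n_epochs × n_rois] array")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    return float(np.mean([spatial_entropy(row) for row in arr]))


def se_table_values(per_epoch_rp_bands: np.ndarray) -> np.ndarray:
    """Per-band SE for one subject from [n_epochs × n_rois × n_bands]."""
    arr = np.asarray(per_epoch_rp_bands, dtype=float)
    return np.array([se_per_subject(arr[:, :, b]) for b in range(arr.shape[2])])


@dataclass(frozen=True)
class SeTable:
    """Subject × band spatial entropy values, all in [0, 1]."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    band_names: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subject_ids), len(self.band_names)):
            raise ValueError("values shape inconsistent with labels")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise ValueError("SE values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "band_names", tuple(self.band_names))

    def to_frame(self) -> pd.DataFrame:
        s, b = np.meshgrid(range(len(self.subject_ids)),
                           range(len(self.band_names)), indexing="ij")
        return pd.DataFrame({
            "subject_id": np.asarray(self.subject_ids)[s.ravel()],
            "band": np.asarray(self.band_names)[b.ravel()],
            "se": self.values.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SeTable":
        subjects = tuple(dict.fromkeys(df["subject_id"].astype(str)))
        bands = tuple(dict.fromkeys(df["band"].astype(str)))
        piv = df.set_index(["subject_id", "band"])["se"]
        v = np.array([[piv.loc[(s, b)] for b in bands] for s in subjects])
        return cls(v, subjects, bands)
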