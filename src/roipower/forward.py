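"""Toy forward model: random full-row-rank lead field over an ROI-labelled
source space.

This is a configurable stand-in for an anatomical head model: it preserves
the *structure* the inverse stage needs (a linear sensor←source gain matrix
and an atlas partition of the sources into R regions, default 68) without
any claim of geometric realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_ATLAS_ROIS = 68


def atlas_labels(n_rois: int = N_ATLAS_ROIS) -> tuple[str, ...]:
    """Cortical parcel names; the 68-region gyrus-based atlas by default."""
    if n_rois == N_ATLAS_ROIS:
        text = (resources.files("roipower") / "data" /
                "desikan_killiany_68.txt").read_text()
        labels = tuple(line.strip() for line in text.splitlines() if line.strip())
        assert len(labels) == N_ATLAS_ROIS
        return labels
    return tuple(f"roi{i + 1:03d}" for i in range(n_rois))


@dataclass(frozen=True)
class ForwardModel:
    """Linear forward operator K with an atlas labelling of its columns.

    lead_field : [n_sensors × n_sources] unitless gain, full row rank
    source_positions : [n_sources × 3] arbitrary units
    roi_labels : per-source ROI name; every ROI owns ≥ 1 source
    """

    lead_field: np.ndarray
    source_positions: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self):
        K = np.asarray(self.lead_field, dtype=float)
        pos = np.asarray(self.source_positions, dtype=float)
        if K.ndim != 2 or K.shape[0] < 3:
            raise ValueError("lead_field must be 2-D with ≥ 3 sensors")
        if not np.all(np.isfinite(K)):
            raise ValueError("lead_field contains non-finite values")
        if np.linalg.matrix_rank(K) < K.shape[0]:
            raise ValueError("lead_field must have full row rank")
        if pos.shape != (K.shape[1], 3):
            raise ValueError("source_positions must be [n_sources × 3]")
        if len(self.roi_labels) != K.shape[1]:
            raise ValueError("one ROI label per source required")
        if np.any(np.all(K == 0.0, axis=0)):
            raise ValueError("lead_field has an all-zero column")
        object.__setattr__(self, "lead_field", K)
        object.__setattr__(self, "source_positions", pos)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_sensors(self) -> int:
        return self.lead_field.shape[0]

    @property
    def n_sources(self) -> int:
        return self.lead_field.shape[1]

    @property
    def rois(self) -> tuple[str, ...]:
        """Unique ROI names in first-appearance (atlas) order."""
        seen: dict[str, None] = {}
        for lab in self.roi_labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def roi_index(self) -> np.ndarray:
        """Integer ROI id per source, following `rois` order."""
        order = {lab: i for i, lab in enumerate(self.rois)}
        return np.array([order[lab] for lab in self.roi_labels], dtype=int)


def make_toy_forward_model(n_sensors: int, n_sources: int,
                           n_rois: int = N_ATLAS_ROIS,
                           seed: int = 0) -> ForwardModel:
    """Random well-conditioned lead field with an even ROI partition.

    Sources are placed uniformly in the unit sphere; gains are i.i.d.
    standard normal with columns scaled to unit norm, so every source
    projects with comparable total gain and sensor amplitudes stay on the
    scale of the source amplitudes (redrawn in the measure-zero event of
    rank deficiency).  ROI labels partition the sources as evenly as
    possible, contiguously: the first ``n_sources mod n_rois`` ROIs get one
    extra source.
    """
    if n_sensors < 3:
        raise ValueError("need at least 3 sensors")
    if not (1 <= n_rois <= n_sources):
        raise ValueError("need n_sources ≥ n_rois ≥ 1")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        K = rng.standard_normal((n_sensors, n_sources))
        K /= np.linalg.norm(K, axis=0, keepdims=True)
        if np.linalg.matrix_rank(K) == n_sensors:
            break
    pos = rng.standard_normal((n_sources, 3))
    pos /= np.maximum(np.linalg.norm(pos, axis=1, keepdims=True), 1e-12)
    pos *= rng.uniform(0.0, 1.0, size=(n_sources, 1)) ** (1.0 / 3.0)
    labels = atlas_labels(n_rois)
    base, extra = divmod(n_sources, n_rois)
    counts = [base + (1 if i < extra else 0) for i in range(n_rois)]
    roi_per_source = tuple(labels[i] for i, c in enumerate(counts) for _ in range(c))
    return ForwardModel(lead_field=K, source_positions=pos,
                        roi_labels=roi_per_source)


def write_forward_model(model: ForwardModel, gain_csv: str | Path,
                        sources_csv: str | Path) -> None:
    """Serialize as a CSV pair: gain matrix, and source table (position + ROI)."""
    pd.DataFrame(model.lead_field).to_csv(gain_csv, index=False)
    df = pd.DataFrame(model.source_positions, columns=["x", "y", "z"])
    df["roi"] = list(model.roi_labels)
    df.to_csv(sources_csv, index=False)


def read_forward_model(gain_csv: str | Path,
                       sources_csv: str | Path) -> ForwardModel:
    K = pd.read_csv(gain_csv).to_numpy(dtype=float)
    df = pd.read_csv(sources_csv)
    return ForwardModel(lead_field=K,
                        source_positions=df[["x", "y", "z"]].to_numpy(float),
                        roi_labels=tuple(df["roi"].astype(str)))
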