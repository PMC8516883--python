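"""Synthetic resting-state EEG cohorts with known spectral ground truth.

Each subject's source activity is a sum of band-limited Gaussian oscillators
(one per frequency band, unit-RMS, scaled by a per-ROI amplitude) plus a
1/f "pink" background.  Amplitudes factor as

    amp(band, ROI, subject) = base_b · effect_b(group) · u_subject,b · v_ROI,b

with log-normal subject (σ = `subject_sigma`) and ROI (σ = `heterogeneity`)
factors, so group effects, between-subject variability, and spatial
heterogeneity are three independent, controllable knobs.  Effect
multipliers apply to the first ("risk") group only.  Because the oscillator
components are normalized to unit sample RMS, the fraction of source
variance in band b is exactly amp_b² / Σ amp² when the background is off —
the ground truth the downstream relative-power stage is tested against.

Band-limiting reuses the analysis-chain FIR designs, so generator and
analysis share band conventions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .filters import bandlimit_noise
from .forward import ForwardModel
from .preprocess import Recording, default_channel_labels
from .spectral import BandScheme

DEFAULT_BAND_AMPLITUDES = {"delta": 2.0, "theta": 1.5, "alpha": 2.0,
                           "beta": 1.0, "gamma": 0.8}

#: demographic composition used for synthetic metadata, per group:
#: (severity histogram over MIL/MOD/SEV, male count, group size)
_DEMOGRAPHICS = {
    "risk": {"severity": (6, 8, 4), "males": 4, "n": 18},
    "protective": {"severity": (17, 8, 10), "males": 12, "n": 35},
}
_MMSE_BY_SEVERITY = {"MIL": (22.4, 2.5), "MOD": (13.3, 2.1), "SEV": (3.7, 4.4)}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-group synthetic cohort.

    Amplitudes are source-level RMS in µV; `effect_multipliers` scale the
    risk group's band amplitudes; `heterogeneity` is the log-normal σ of
    the ROI-to-ROI amplitude spread (per band or scalar); `subject_sigma`
    is the log-normal σ of the between-subject amplitude spread;
    `noise_amplitude` is the RMS of the 1/f background (power ∝ 1/f over
    the analysis range).
    """

    n_subjects_per_group: tuple[int, int] = (18, 35)
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    effect_multipliers: Mapping[str, float] = field(default_factory=dict)
    heterogeneity: float | Mapping[str, float] = 0.3
    subject_sigma: float = 0.15
    noise_amplitude: float = 1.0
    duration_s: float = 300.0
    fs_hz: float = 500.0
    groups: tuple[str, str] = ("risk", "protective")
    scheme: BandScheme = field(default_factory=BandScheme)
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_subjects_per_group):
            raise ValueError("group sizes must be nonnegative")
        if self.fs_hz <= 2.0 * self.scheme.f_max:
            raise ValueError("fs_hz must exceed twice the highest band edge")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in self.band_amplitudes:
            self.scheme.edges(name)  # KeyError on unknown band
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be nonnegative")
        if any(m < 0 for m in self.effect_multipliers.values()):
            raise ValueError("effect multipliers must be nonnegative")
        if self.noise_amplitude < 0 or self.subject_sigma < 0:
            raise ValueError("noise_amplitude and subject_sigma must be ≥ 0")
        if np.any(np.asarray(list(self._het_map().values())) < 0):
            raise ValueError("heterogeneity must be nonnegative")

    def _het_map(self) -> dict[str, float]:
        if isinstance(self.heterogeneity, Mapping):
            return {b: float(self.heterogeneity.get(b, 0.0))
                    for b in self.scheme.names}
        return {b: float(self.heterogeneity) for b in self.scheme.names}

    def amplitude(self, band: str) -> float:
        return float(self.band_amplitudes.get(band, 0.0))

    def multiplier(self, band: str, group: str) -> float:
        if group not in self.groups:
            raise ValueError(f"unknown group label {group!r}")
        if group == self.groups[0]:
            return float(self.effect_multipliers.get(band, 1.0))
        return 1.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


def pink_noise(shape: tuple[int, ...], fs_hz: float,
               rng: np.random.Generator, f_lo: float = 1.0,
               f_hi: float = 70.0) -> np.ndarray:
    """Unit-RMS noise with power ∝ 1/f on [f_lo, f_hi], zero outside.

    Synthesized spectrally: complex Gaussian Fourier coefficients shaped by
    1/√f inside the range.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = np.zeros_like(freqs)
    in_range = (freqs >= f_lo) & (freqs <= f_hi)
    gain[in_range] = 1.0 / np.sqrt(freqs[in_range])
    coef = rng.standard_normal(shape[:-1] + (freqs.size,)) \
        + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))
    x = np.fft.irfft(coef * gain, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-300)


def _unit_band_noise(shape: tuple[int, ...], lo: float, hi: float,
                     fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    comp = bandlimit_noise(white, lo, hi, fs_hz)
    sd = comp.std(axis=-1, keepdims=True)
    return comp / np.maximum(sd, 1e-300)


def _generate_sources(spec: CohortSpec, group_label: str, model: ForwardModel,
                      rng: np.random.Generator):
    """Source time series [n_sources × n_samples] plus the ground-truth
    per-band subject amplitudes and per-ROI amplitude draws."""
    if group_label not in spec.groups:
        raise ValueError(f"unknown group label {group_label!r}")
    n = spec.n_samples
    roi_idx = model.roi_index()
    n_rois = model.n_rois
    het = spec._het_map()
    sources = np.zeros((model.n_sources, n))
    truth_subject: dict[str, float] = {}
    truth_roi: dict[str, np.ndarray] = {}
    for name, lo, hi in spec.scheme.bands:
        base = spec.amplitude(name) * spec.multiplier(name, group_label)
        subj = rng.lognormal(0.0, spec.subject_sigma)
        roi_amp = base * subj * rng.lognormal(0.0, het[name], size=n_rois)
        truth_subject[name] = base * subj
        truth_roi[name] = roi_amp
        if base == 0.0:
            continue
        comp = _unit_band_noise((model.n_sources, n), lo, hi, spec.fs_hz, rng)
        sources += roi_amp[roi_idx, None] * comp
    if spec.noise_amplitude > 0.0:
        sources += spec.noise_amplitude * pink_noise(
            (model.n_sources, n), spec.fs_hz, rng,
            spec.scheme.f_min, spec.scheme.f_max)
    return sources, truth_subject, truth_roi


def generate_subject(spec: CohortSpec, group_label: str, model: ForwardModel,
                     subject_seed: int, *, with_truth: bool = False):
    """Sensor-space recording for one subject: data = lead_field × sources."""
    rng = np.random.default_rng(subject_seed)
    sources, truth, _ = _generate_sources(spec, group_label, model, rng)
    rec = Recording(data=model.lead_field @ sources, fs_hz=spec.fs_hz,
                    channel_labels=default_channel_labels(model.n_sensors))
    return (rec, truth) if with_truth else rec


def generate_subject_roi(spec: CohortSpec, group_label: str,
                         model: ForwardModel, subject_seed: int, *,
                         with_truth: bool = False):
    """ROI-level bypass output: member sources summed per ROI.

    Skips the sensor/inverse stages entirely, so the spectral, entropy and
    statistics stages can be exercised against generator ground truth.
    Returns ``[n_rois × n_samples]`` following `model.rois` order.
    """
    rng = np.random.default_rng(subject_seed)
    sources, truth, _ = _generate_sources(spec, group_label, model, rng)
    roi_idx = model.roi_index()
    data = np.zeros((model.n_rois, sources.shape[1]))
    np.add.at(data, roi_idx, sources)
    return (data, truth) if with_truth else data


def _subject_metadata(spec: CohortSpec, group: str, subject_id: str,
                      seed: int, truth: Mapping[str, float],
                      rng: np.random.Generator) -> dict:
    demo = _DEMOGRAPHICS.get(group, {"severity": (1, 1, 1), "males": 1, "n": 2})
    sev_p = np.asarray(demo["severity"], float)
    severity = rng.choice(["MIL", "MOD", "SEV"], p=sev_p / sev_p.sum())
    sex = "M" if rng.random() < demo["males"] / demo["n"] else "F"
    mu, sd = _MMSE_BY_SEVERITY[severity]
    row = {
        "subject_id": subject_id, "group": group, "seed": int(seed),
        "sex": sex, "severity": severity,
        "age": float(np.clip(rng.normal(80.6, 6.5), 65.0, 100.0)),
        "mmse": float(np.clip(round(rng.normal(mu, sd)), 0, 30)),
    }
    row.update({f"amp_{band}": float(a) for band, a in truth.items()})
    return row


def generate_cohort(spec: CohortSpec, model: ForwardModel,
                    seed: int | None = None, *, bypass: bool = False):
    """Generate both groups; returns ``(signals, metadata)``.

    `signals` is a list of `Recording` (or of ROI arrays when
    ``bypass=True``) aligned with the metadata rows; per-subject seeds are
    derived reproducibly from the master seed and recorded in the metadata
    together with the ground-truth subject amplitudes.
    """
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    total = sum(spec.n_subjects_per_group)
    seeds = rng.integers(0, 2**31 - 1, size=max(total, 1))
    signals, rows = [], []
    k = 0
    make = generate_subject_roi if bypass else generate_subject
    for group, n_group in zip(spec.groups, spec.n_subjects_per_group):
        for _ in range(n_group):
            sid = f"S{k + 1:03d}"
            out, truth = make(spec, group, model, int(seeds[k]),
                              with_truth=True)
            signals.append(out)
            rows.append(_subject_metadata(spec, group, sid, int(seeds[k]),
                                          truth, rng))
            k += 1
    columns = (["subject_id", "group", "seed", "sex", "severity", "age",
                "mmse"] + [f"amp_{b}" for b in spec.scheme.names])
    metadata = pd.DataFrame(rows, columns=columns)
    return signals, metadata


def inject_transient(rec: Recording, time_s: float, amplitude_uv: float = 500.0,
                     channel: int = 0, width_s: float = 0.05) -> Recording:
    """Add a Gaussian transient (a crude movement-artifact surrogate) so the
    epoch-rejection stage has something to catch."""
    t = np.arange(rec.n_samples) / rec.fs_hz
    bump = amplitude_uv * np.exp(-0.5 * ((t - time_s) / width_s) ** 2)
    data = rec.data.copy()
    data[channel] += bump
    return rec.with_data(data)
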