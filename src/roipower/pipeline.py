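"""End-to-end orchestration: recordings (or a synthetic cohort) → RP/SE
tables → group statistics → CSV artifacts, under a single validated,
serializable configuration with one master seed."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .entropy import SeTable, se_table_values
from .forward import ForwardModel, make_toy_forward_model, read_forward_model
from .inverse import RoiSignals, build_inverse, extract_roi_signals
from .io import read_metadata, read_recording, write_cohort
from .preprocess import Recording, preprocess_recording, segment_epochs
from .spectral import BandScheme, RpTable, rp_per_subject, subject_normalized_psd
from .stats import GroupComparison, compare_groups
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("roipower")

SEVERITY_LEVELS = ("control", "MIL", "MOD", "SEV")


class ConfigError(ValueError):
    """Invalid pipeline configuration (distinct from data errors)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a run; defaults mirror the study's printed parameters
    (500 Hz, 1–70 Hz analysis band, 50 Hz notch, 5 s epochs, 68 ROIs,
    α = 0.05, q = 0.05)."""

    mode: str = "synthetic"                 # synthetic | ascii | edf
    input_dir: str | None = None
    metadata_csv: str | None = None
    output_dir: str = "roipower_out"
    seed: int = 0
    # preprocessing
    fs_hz: float = 500.0
    notch_hz: float = 50.0
    band_lo_hz: float = 1.0
    band_hi_hz: float = 70.0
    epoch_length_s: float = 5.0
    ptp_threshold_uv: float = 150.0
    z_threshold: float = 4.0
    # inverse stage
    source_mode: str = "inverse"            # inverse | bypass (synthetic only)
    inverse_alpha: float | None = None      # None → near-noiseless default
    roi_aggregate: str = "mean"
    forward_gain_csv: str | None = None
    forward_sources_csv: str | None = None
    toy_n_sensors: int = 19
    toy_n_sources: int = 68
    toy_n_rois: int = 68
    forward_seed: int = 0
    # spectral / statistics
    psd_method: str = "welch"
    q: float = 0.05
    alpha: float = 0.05
    u_convention: str = "first"
    # synthetic cohort overrides (CohortSpec keyword arguments)
    cohort: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "ascii", "edf"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode != "synthetic":
            if not self.input_dir:
                raise ConfigError("input_dir required for file modes")
            if self.source_mode == "bypass":
                raise ConfigError("bypass source_mode is synthetic-only")
        if self.source_mode not in ("inverse", "bypass"):
            raise ConfigError(f"unknown source_mode {self.source_mode!r}")
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ConfigError("invalid analysis band")
        if self.epoch_length_s <= 0:
            raise ConfigError("epoch_length_s must be positive")
        if not (0 < self.q <= 1 and 0 < self.alpha <= 1):
            raise ConfigError("q and alpha must lie in (0, 1]")
        if bool(self.forward_gain_csv) != bool(self.forward_sources_csv):
            raise ConfigError("forward model needs both CSV paths")
        try:
            self._cohort_spec(BandScheme())
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid cohort spec: {exc}") from exc

    def _cohort_spec(self, scheme: BandScheme) -> CohortSpec:
        kw: dict[str, Any] = dict(self.cohort)
        if "n_subjects_per_group" in kw:
            kw["n_subjects_per_group"] = tuple(kw["n_subjects_per_group"])
        kw.setdefault("seed", self.seed)
        return CohortSpec(scheme=scheme, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    rp: RpTable
    se: SeTable
    comparison: GroupComparison | None
    qc: pd.DataFrame
    metadata: pd.DataFrame
    paths: dict[str, Path]


def _forward_model(config: PipelineConfig) -> ForwardModel:
    if config.forward_gain_csv:
        return read_forward_model(config.forward_gain_csv,
                                  config.forward_sources_csv)
    return make_toy_forward_model(config.toy_n_sensors, config.toy_n_sources,
                                  config.toy_n_rois, seed=config.forward_seed)


def _load_recordings(config: PipelineConfig):
    in_dir = Path(config.input_dir)
    exts = (".edf",) if config.mode == "edf" else (".csv", ".txt", ".asc")
    paths = sorted(p for p in in_dir.iterdir()
                   if p.suffix.lower() in exts and p.stem != "metadata")
    if not paths:
        raise FileNotFoundError(f"no recordings found in {in_dir}")
    recs = [read_recording(p, fs_hz=config.fs_hz) for p in paths]
    if config.metadata_csv:
        meta = read_metadata(config.metadata_csv)
    elif (in_dir / "metadata.csv").exists():
        meta = read_metadata(in_dir / "metadata.csv")
    else:
        raise FileNotFoundError("metadata CSV is required for file modes")
    order = {sid: i for i, sid in enumerate(meta["subject_id"].astype(str))}
    recs = [rec for _, rec in sorted(zip(paths, recs),
                                     key=lambda t: order.get(t[0].stem, 1 << 30))]
    return recs, meta


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage and write the run artifacts to `output_dir`."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = BandScheme(f_min=config.band_lo_hz, f_max=config.band_hi_hz) \
        if (config.band_lo_hz, config.band_hi_hz) != (1.0, 70.0) else BandScheme()
    model = _forward_model(config)

    if config.mode == "synthetic":
        spec = config._cohort_spec(scheme)
        signals, metadata = generate_cohort(
            spec, model, seed=config.seed,
            bypass=config.source_mode == "bypass")
        fs = spec.fs_hz
        metadata.to_csv(out / "metadata.csv", index=False)
    else:
        signals, metadata = _load_recordings(config)
        fs = config.fs_hz

    op = build_inverse(model, config.inverse_alpha) \
        if config.source_mode == "inverse" else None

    subj_rp, subj_se, psd_rows, qc_rows, kept_ids = [], [], [], [], []
    freqs_ref = None
    for sig, sid in zip(signals, metadata["subject_id"].astype(str)):
        if config.source_mode == "bypass":
            roi_rec = Recording(data=sig, fs_hz=fs,
                                channel_labels=model.rois)
            epochs = segment_epochs(roi_rec, config.epoch_length_s)
            n_total = epochs.n_epochs
            roi = RoiSignals(data=epochs.epochs, roi_labels=model.rois,
                             fs_hz=fs)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                epochs = preprocess_recording(
                    sig, notch_hz=config.notch_hz,
                    band=(config.band_lo_hz, config.band_hi_hz),
                    epoch_length_s=config.epoch_length_s,
                    ptp_threshold_uv=config.ptp_threshold_uv,
                    z_threshold=config.z_threshold)
            n_total = int(sig.n_samples // round(config.epoch_length_s * fs))
            roi = extract_roi_signals(op, epochs, model,
                                      aggregate=config.roi_aggregate) \
                if epochs.n_epochs else None
        qc_rows.append({"subject_id": sid, "n_epochs_total": n_total,
                        "n_epochs_kept": epochs.n_epochs})
        if epochs.n_epochs == 0:
            log.warning("subject %s: all epochs rejected; excluded", sid)
            continue
        mean_rp, per_epoch = rp_per_subject(roi, scheme,
                                            method=config.psd_method)
        subj_rp.append(mean_rp)
        subj_se.append(se_table_values(per_epoch))
        freqs_ref, npsd = subject_normalized_psd(roi, scheme,
                                                 method=config.psd_method)
        psd_rows.append(npsd)
        kept_ids.append(sid)

    if not kept_ids:
        raise RuntimeError("no subject retained any artifact-free epoch")
    rp = RpTable(np.stack(subj_rp), tuple(kept_ids), model.rois, scheme.names)
    se = SeTable(np.stack(subj_se), tuple(kept_ids), scheme.names)
    qc = pd.DataFrame(qc_rows)
    meta_kept = metadata[metadata["subject_id"].astype(str).isin(kept_ids)]

    comparison = None
    if meta_kept["group"].nunique() == 2 and \
            meta_kept["group"].value_counts().min() >= 2:
        comparison = compare_groups(rp, se, meta_kept, q=config.q,
                                    alpha=config.alpha,
                                    u_convention=config.u_convention)

    psd_df = pd.DataFrame({
        "subject_id": np.repeat(kept_ids, freqs_ref.size),
        "freq_hz": np.tile(freqs_ref, len(kept_ids)),
        "psd_n": np.concatenate(psd_rows),
    })
    grand = summarize_psd_by_group(psd_df, meta_kept) \
        if "severity" in meta_kept.columns else None
    spider = band_rp_summary(rp, meta_kept) \
        if "severity" in meta_kept.columns else None

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame | None):
        if df is None:
            return
        p = out / name
        df.to_csv(p, index=False, float_format="%.12g")
        paths[name] = p

    _write("rp.csv", rp.to_long_frame())
    _write("rp_wide.csv", rp.to_wide_frame())
    _write("se.csv", se.to_frame())
    _write("qc.csv", qc)
    _write("stats.csv", comparison.results if comparison else None)
    _write("psd_subjects.csv", psd_df)
    _write("grand_average_psd.csv", grand)
    _write("band_rp_summary.csv", spider)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"roipower": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "subjects_kept": kept_ids,
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = mp
    return RunResult(rp=rp, se=se, comparison=comparison, qc=qc,
                     metadata=metadata, paths=paths)


def _check_severity(metadata: pd.DataFrame, severity_col: str) -> pd.DataFrame:
    if severity_col not in metadata.columns:
        raise ValueError(f"metadata lacks a {severity_col!r} column")
    sev = metadata[severity_col].astype(str)
    unknown = set(sev) - set(SEVERITY_LEVELS)
    if unknown:
        raise ValueError(f"unknown severity labels: {sorted(unknown)}")
    return metadata.assign(**{severity_col: sev})


def summarize_psd_by_group(psd_df: pd.DataFrame, metadata: pd.DataFrame,
                           severity_col: str = "severity") -> pd.DataFrame:
    """Grand-averaged normalized spectra per (group, severity stage).

    `psd_df` holds per-subject normalized spectra (columns subject_id,
    freq_hz, psd_n); severity labels must come from {control, MIL, MOD, SEV}.
    """
    meta = _check_severity(metadata, severity_col)
    merged = psd_df.merge(meta[["subject_id", "group", severity_col]],
                          on="subject_id", how="inner")
    out = (merged.groupby(["group", severity_col, "freq_hz"], sort=True,
                          as_index=False)["psd_n"].mean())
    return out.rename(columns={severity_col: "severity"})


def band_rp_summary(rp: RpTable, metadata: pd.DataFrame,
                    severity_col: str = "severity") -> pd.DataFrame:
    """Spider-plot table: mean RP per (group, severity, band), averaged over
    subjects and ROIs."""
    meta = _check_severity(metadata, severity_col)
    long = rp.to_long_frame().merge(
        meta[["subject_id", "group", severity_col]], on="subject_id")
    out = (long.groupby(["group", severity_col, "band"], sort=False,
                        as_index=False)["rp"].mean())
    return out.rename(columns={severity_col: "severity"})


def simulate_cohort(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate and write a sensor-space cohort (per-subject ASCII + metadata)."""
    config.validate()
    scheme = BandScheme()
    spec = config._cohort_spec(scheme)
    model = _forward_model(config)
    recs, metadata = generate_cohort(spec, model, seed=config.seed)
    write_cohort(recs, metadata, out_dir)
    return Path(out_dir)
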