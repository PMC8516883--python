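"""Size and power simulation for the global per-band group test.

Runs many synthetic cohorts through the ROI-bypass → relative-power →
Mann–Whitney chain and reports, per band, how often the global test (on
subject-level ROI-averaged RP) rejects at α.  With no group effect this
estimates the empirical type-I error; with an effect multiplier it
estimates power.  Cohorts are deliberately small (one 5 s epoch per
subject by default) — between-subject amplitude dispersion, not epoch
count, dominates the test's operating characteristics.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .forward import make_toy_forward_model
from .inverse import RoiSignals
from .spectral import rp_per_subject
from .stats import mann_whitney_u
from .synthetic import CohortSpec, generate_cohort


def cohort_global_pvalues(spec: CohortSpec, seed: int,
                          model=None) -> np.ndarray:
    """Per-band p-values of the global group test for one simulated cohort."""
    if model is None:
        model = make_toy_forward_model(8, 68, 68, seed=0)
    signals, meta = generate_cohort(spec, model, seed=seed, bypass=True)
    n_per = int(round(5.0 * spec.fs_hz))
    roi_means = []
    for data in signals:
        n_ep = data.shape[1] // n_per
        epochs = data[:, :n_ep * n_per].reshape(data.shape[0], n_ep, n_per)
        roi = RoiSignals(data=epochs.swapaxes(0, 1), roi_labels=model.rois,
                         fs_hz=spec.fs_hz)
        mean_rp, _ = rp_per_subject(roi, spec.scheme)
        roi_means.append(mean_rp.mean(axis=0))
    roi_means = np.asarray(roi_means)
    groups = meta["group"].to_numpy()
    g1, g2 = spec.groups
    return np.array([
        mann_whitney_u(roi_means[groups == g1, b],
                       roi_means[groups == g2, b]).p_value
        for b in range(spec.scheme.n_bands)])


def rejection_rates(n_cohorts: int, seed: int, *,
                    effect_multipliers: Mapping[str, float] | None = None,
                    n_rois: int = 68,
                    n_subjects_per_group: tuple[int, int] = (18, 35),
                    duration_s: float = 5.0, fs_hz: float = 200.0,
                    alpha: float = 0.05) -> np.ndarray:
    """Per-band rejection rate of the global test over `n_cohorts` cohorts.

    Cohort seeds are drawn reproducibly from `seed`.  Returns an array of
    length n_bands following the default band order.
    """
    spec = CohortSpec(n_subjects_per_group=n_subjects_per_group,
                      duration_s=duration_s, fs_hz=fs_hz,
                      effect_multipliers=dict(effect_multipliers or {}))
    model = make_toy_forward_model(8, n_rois, n_rois, seed=0)
    rng = np.random.default_rng(seed)
    cohort_seeds = rng.integers(0, 2**31 - 1, size=n_cohorts)
    p = np.array([cohort_global_pvalues(spec, int(s), model)
                  for s in cohort_seeds])
    return (p < alpha).mean(axis=0)
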