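"""Nonparametric group comparison of RP/SE tables.

Mann–Whitney U between the two genotype groups (exact null distribution
for small tie-free samples, tie- and continuity-corrected normal
approximation otherwise), Benjamini–Hochberg FDR across the per-ROI family
within each band, Pearson χ² for demographic matching tables, and advisory
normality/homoscedasticity checks (the pipeline proceeds nonparametrically
regardless, as RP/SE distributions do not meet parametric assumptions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .entropy import SeTable
from .spectral import RpTable


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided", *,
                   statistic_of: str = "first") -> TestResult:
    """Mann–Whitney U test; reports U of the first sample by default.

    Uses the exact null distribution when n1+n2 ≤ 20 and the pooled sample
    is tie-free, otherwise the normal approximation with tie correction and
    continuity correction.  ``statistic_of="min"`` reports min(U, n1·n2−U)
    instead (the textbook convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    u = float(res.statistic)
    if statistic_of == "min":
        u = min(u, x.size * y.size - u)
    elif statistic_of != "first":
        raise ValueError(f"unknown U convention {statistic_of!r}")
    return TestResult(statistic=u, p_value=float(res.pvalue),
                      n1=x.size, n2=y.size, method=f"mann-whitney-{method}")


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05):
    """Step-up BH FDR: returns (adjusted p-values, rejection flags at `q`)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def pearson_chi2(table: np.ndarray) -> TestResult:
    """Pearson χ² of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      n1=t.shape[0], n2=t.shape[1], method="pearson-chi2")


def distribution_checks(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Advisory exploration: per-group KS normality (against the fitted
    normal) and Levene homoscedasticity across groups."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    rows = []
    for name, arr in arrays.items():
        sd = arr.std(ddof=1)
        if sd == 0:
            stat, p = np.inf, 0.0
        else:
            stat, p = sps.kstest(arr, "norm", args=(arr.mean(), sd))
        rows.append({"test": "ks-normality", "group": name,
                     "statistic": float(stat), "p_value": float(p)})
    if len(arrays) >= 2:
        stat, p = sps.levene(*arrays.values())
        rows.append({"test": "levene", "group": "all",
                     "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Tidy per-(metric, band, ROI) test results.

    `results` columns: metric (rp|se), band, roi ("global" for the
    band-level test on ROI-averaged values), statistic (U), p_raw, p_adj,
    significant.  p_adj equals p_raw for global and SE rows — the FDR
    family is the 68 ROIs within each band, nothing else is corrected.
    """

    results: pd.DataFrame
    groups: tuple[str, str]
    q: float
    alpha: float

    def subset(self, metric: str, band: str | None = None) -> pd.DataFrame:
        out = self.results[self.results["metric"] == metric]
        if band is not None:
            out = out[out["band"] == band]
        return out

    def global_p(self, metric: str, band: str) -> float:
        sub = self.subset(metric, band)
        return float(sub.loc[sub["roi"] == "global", "p_raw"].iloc[0])

    def n_significant_rois(self, band: str) -> int:
        sub = self.subset("rp", band)
        return int(sub.loc[sub["roi"] != "global", "significant"].sum())


def _ordered_groups(metadata: pd.DataFrame,
                    group_order: tuple[str, str] | None) -> tuple[str, str]:
    present = list(dict.fromkeys(metadata["group"].astype(str)))
    if group_order is not None:
        missing = set(group_order) - set(present)
        if missing:
            raise ValueError(f"groups {missing} absent from metadata")
        return group_order
    if set(present) == {"risk", "protective"}:
        return ("risk", "protective")
    if len(present) != 2:
        raise ValueError("exactly two groups are required")
    return tuple(sorted(present))  # type: ignore[return-value]


def compare_groups(rp: RpTable, se: SeTable | None, metadata: pd.DataFrame,
                   q: float = 0.05, alpha: float = 0.05, *,
                   group_order: tuple[str, str] | None = None,
                   u_convention: str = "first") -> GroupComparison:
    """Full comparison between the two groups of a cohort.

    (a) per band, a global U test on subject-level ROI-averaged RP;
    (b) per band, per-ROI U tests BH-corrected across the ROI family;
    (c) per band, a U test on SE (when an SE table is given).
    """
    meta = metadata.set_index(metadata["subject_id"].astype(str))
    groups = _ordered_groups(metadata, group_order)
    idx = {g: [i for i, s in enumerate(rp.subject_ids)
               if meta.loc[s, "group"] == g] for g in groups}
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("need at least 2 subjects per group")
    g1, g2 = groups
    rows = []
    for b, band in enumerate(rp.band_names):
        vals = rp.values[:, :, b]
        roi_mean = vals.mean(axis=1)
        res = mann_whitney_u(roi_mean[idx[g1]], roi_mean[idx[g2]],
                             statistic_of=u_convention)
        rows.append({"metric": "rp", "band": band, "roi": "global",
                     "statistic": res.statistic, "p_raw": res.p_value,
                     "p_adj": res.p_value,
                     "significant": res.p_value <= alpha})
        p_roi, u_roi = [], []
        for r in range(len(rp.roi_labels)):
            res_r = mann_whitney_u(vals[idx[g1], r], vals[idx[g2], r],
                                   statistic_of=u_convention)
            p_roi.append(res_r.p_value)
            u_roi.append(res_r.statistic)
        p_adj, flags = benjamini_hochberg(p_roi, q=q)
        for r, roi in enumerate(rp.roi_labels):
            rows.append({"metric": "rp", "band": band, "roi": roi,
                         "statistic": u_roi[r], "p_raw": p_roi[r],
                         "p_adj": float(p_adj[r]),
                         "significant": bool(flags[r])})
    if se is not None:
        for b, band in enumerate(se.band_names):
            res = mann_whitney_u(se.values[idx[g1], b], se.values[idx[g2], b],
                                 statistic_of=u_convention)
            rows.append({"metric": "se", "band": band, "roi": "global",
                         "statistic": res.statistic, "p_raw": res.p_value,
                         "p_adj": res.p_value,
                         "significant": res.p_value <= alpha})
    return GroupComparison(results=pd.DataFrame(rows), groups=groups,
                           q=q, alpha=alpha)
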