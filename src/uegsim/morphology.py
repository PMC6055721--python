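"""Morphology-correlation statistics for recorded vs. simulated electrograms.

Similarity between matched electrograms is quantified by Pearson correlation
over the entire beat as well as over the QRS complex and the T-wave
separately.  Signed areas under the QRS and T-wave (trapezoidal integrals of
the baseline-corrected voltage, mV*ms) summarize morphology per site: the
model predicts a strongly positive correlation between activation time and
QRS area (early sites show net-negative QS complexes, late sites net-positive
R waves) and a strongly negative one between repolarization time and T-wave
area.

Cohort distributions are described by the median, the median absolute
deviation, the quartiles, and Tukey outlier fences (Q1 - 1.5*IQR,
Q3 + 1.5*IQR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import BeatWindows
from .signals import SignalMatrix, SignalTrace

__all__ = [
    "pearson_cc",
    "window_area",
    "estimate_baseline",
    "SummaryStats",
    "summarize",
    "MorphologyReport",
    "morphology_compare",
    "timing_area_maps",
]


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def estimate_baseline(trace: SignalTrace, pre_stim_ms: float = 20.0) -> float:
    """Isoelectric reference: median of the last ``pre_stim_ms`` before the stimulus.

    Falls back to the first sample when the trace carries no pre-stimulus data
    (stimulus-aligned beats with ``t0 >= 0``).
    """
    if trace.t0 < 0:
        mask = (trace.times >= -pre_stim_ms) & (trace.times < 0)
        if mask.sum() >= 1:
            return float(np.median(trace.samples[mask]))
    return float(trace.samples[0])


def window_area(trace: SignalTrace, window: tuple[float, float], baseline: float = 0.0) -> float:
    """Signed trapezoidal area (mV*ms) of ``V - baseline`` over a window.

    Net-negative complexes (QS morphology) yield negative areas.
    """
    mask = trace.window_mask(*window)
    if mask.sum() < 2:
        raise ValueError("area window must contain at least 2 samples")
    return float(np.trapezoid(trace.samples[mask] - baseline, trace.times[mask]))


@dataclass(frozen=True)
class SummaryStats:
    """Median / MAD / quartile summary with Tukey outlier fences."""

    median: float
    mad: float
    q1: float
    q3: float
    lower_fence: float
    upper_fence: float
    n: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError("cannot summarize an empty series")
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))  # linear ("type 7") quartiles
        iqr = q3 - q1
        return cls(med, mad, q1, q3, q1 - 1.5 * iqr, q3 + 1.5 * iqr, int(values.size))

    def outliers(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values outside the Tukey fences."""
        values = np.asarray(values, dtype=float)
        return (values < self.lower_fence) | (values > self.upper_fence)

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "mad": self.mad,
            "q1": self.q1,
            "q3": self.q3,
            "lower_fence": self.lower_fence,
            "upper_fence": self.upper_fence,
            "n": self.n,
        }


def summarize(values: np.ndarray) -> SummaryStats:
    """Median, MAD, quartiles, and outlier fences of a series."""
    return SummaryStats.from_values(values)


@dataclass
class MorphologyReport:
    """Per-site morphology metrics and their cohort summaries."""

    per_site: pd.DataFrame
    summaries: dict[str, SummaryStats]
    cc_qrs_area: float
    cc_twave_area: float

    def to_csv(self, path) -> None:
        self.per_site.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        out = {k: v.as_dict() for k, v in self.summaries.items()}
        out["cc_qrs_area"] = self.cc_qrs_area
        out["cc_twave_area"] = self.cc_twave_area
        return out


def _masked_cc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise Pearson cc between two matrices restricted to a column mask."""
    x = a[:, mask]
    y = b[:, mask]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (xc * yc).sum(axis=1) / denom
    cc[denom == 0] = np.nan
    return cc


def morphology_compare(
    recorded: SignalMatrix,
    simulated: SignalMatrix,
    windows: BeatWindows,
    artifact_blank_ms: float = 10.0,
) -> MorphologyReport:
    """Site-by-site morphological comparison of two matched signal matrices.

    Pearson correlations are computed over the entire beat (excluding the
    first ``artifact_blank_ms`` after the stimulus, where paced recordings
    carry an artifact the model does not produce), the QRS window, and the
    T-wave window; signed QRS/T-wave areas are computed for both matrices and
    correlated across sites.
    """
    if recorded.n_sites != simulated.n_sites:
        raise ValueError("recorded and simulated matrices must have matching site sets")
    if not recorded.same_grid(simulated):
        raise ValueError("recorded and simulated matrices must share the time grid")
    t = recorded.times
    whole = t >= recorded.t0 + artifact_blank_ms
    qrs = (t >= windows.qrs[0]) & (t <= windows.qrs[1])
    tw = (t >= windows.twave[0]) & (t <= windows.twave[1])

    cc_whole = _masked_cc(recorded.data, simulated.data, whole)
    cc_qrs = _masked_cc(recorded.data, simulated.data, qrs)
    cc_tw = _masked_cc(recorded.data, simulated.data, tw)

    def areas(mat: SignalMatrix, mask: np.ndarray) -> np.ndarray:
        out = np.empty(mat.n_sites)
        for i in range(mat.n_sites):
            tr = mat.trace(i)
            out[i] = float(np.trapezoid(tr.samples[mask] - estimate_baseline(tr), t[mask]))
        return out

    qrs_area_rec = areas(recorded, qrs)
    qrs_area_sim = areas(simulated, qrs)
    tw_area_rec = areas(recorded, tw)
    tw_area_sim = areas(simulated, tw)

    per_site = pd.DataFrame(
        {
            "site_id": recorded.site_ids,
            "cc_whole": cc_whole,
            "cc_qrs": cc_qrs,
            "cc_twave": cc_tw,
            "qrs_area_recorded": qrs_area_rec,
            "qrs_area_simulated": qrs_area_sim,
            "twave_area_recorded": tw_area_rec,
            "twave_area_simulated": tw_area_sim,
        }
    )
    summaries = {
        name: SummaryStats.from_values(per_site[name].to_numpy())
        for name in ("cc_whole", "cc_qrs", "cc_twave", "qrs_area_recorded", "qrs_area_simulated", "twave_area_recorded", "twave_area_simulated")
    }
    cc_qa = pearson_cc(qrs_area_rec, qrs_area_sim) if recorded.n_sites >= 3 else float("nan")
    cc_ta = pearson_cc(tw_area_rec, tw_area_sim) if recorded.n_sites >= 3 else float("nan")
    return MorphologyReport(per_site=per_site, summaries=summaries, cc_qrs_area=cc_qa, cc_twave_area=cc_ta)


def timing_area_maps(
    at: np.ndarray,
    rt: np.ndarray,
    qrs_area: np.ndarray,
    twave_area: np.ndarray,
    min_sites: int = 10,
) -> tuple[float, float]:
    """Correlations cc(AT, QRS area) and cc(RT, T-wave area) across sites.

    Requires at least ``min_sites`` sites with finite values in all four
    series; degenerate (constant-timing) inputs yield NaN.
    """
    at = np.asarray(at, dtype=float)
    rt = np.asarray(rt, dtype=float)
    qrs_area = np.asarray(qrs_area, dtype=float)
    twave_area = np.asarray(twave_area, dtype=float)
    ok = np.isfinite(at) & np.isfinite(rt) & np.isfinite(qrs_area) & np.isfinite(twave_area)
    if ok.sum() < min_sites:
        raise ValueError(f"timing-area maps need at least {min_sites} valid sites")
    return pearson_cc(at[ok], qrs_area[ok]), pearson_cc(rt[ok], twave_area[ok])
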