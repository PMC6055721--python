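"""Derivative-based activation/repolarization markers on unipolar electrograms.

Standard definitions: the activation time (AT) is the instant of the steepest
negative slope of the electrogram within the QRS complex; the repolarization
time (RT) is the instant of the steepest positive slope within the T-wave,
regardless of T-wave polarity (the Wyatt method); the activation-recovery
interval is ARI = RT - AT, a surrogate for the local action-potential
duration.  Both markers are invariant to gain and offset changes of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .signals import SignalMatrix, SignalTrace

logger = logging.getLogger(__name__)

__all__ = [
    "BeatWindows",
    "MarkerResult",
    "MarkerMap",
    "detect_at",
    "detect_rt",
    "compute_ari",
    "mark_all",
    "auto_windows",
    "windows_from_timing",
]

#: derivative range (mV/ms) below which a window is considered flat
FLAT_EPS = 1e-9


@dataclass(frozen=True)
class BeatWindows:
    """QRS and T-wave search windows, in ms from the stimulus."""

    qrs: tuple[float, float]
    twave: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.qrs[0] < self.qrs[1] and self.twave[0] < self.twave[1]):
            raise ValueError("windows must have positive length")
        if self.qrs[1] > self.twave[0]:
            raise ValueError("QRS window must end before the T-wave window starts")


class MarkerResult(NamedTuple):
    time_ms: float  # NaN when invalid
    valid: bool
    reason: str  # "ok", "flat", ...


def _window_slice(trace: SignalTrace, window: tuple[float, float]) -> np.ndarray:
    mask = trace.window_mask(*window)
    if mask.sum() < 3:
        raise ValueError("marker window must contain at least 3 samples")
    return mask


def detect_at(trace: SignalTrace, qrs_window: tuple[float, float]) -> MarkerResult:
    """AT as the time of the minimum first derivative inside the QRS window.

    Ties are broken by the earliest sample; a window whose derivative range is
    below ``FLAT_EPS`` is flagged ``"flat"``.
    """
    mask = _window_slice(trace, qrs_window)
    dv = trace.derivative()[mask]
    if np.ptp(dv) < FLAT_EPS:
        return MarkerResult(float("nan"), False, "flat")
    t = trace.times[mask]
    return MarkerResult(float(t[int(np.argmin(dv))]), True, "ok")


def detect_rt(trace: SignalTrace, twave_window: tuple[float, float]) -> MarkerResult:
    """RT by the Wyatt method: time of the maximum first derivative in the T-wave window.

    The same rule applies to positive, negative, and biphasic T-waves.
    """
    mask = _window_slice(trace, twave_window)
    dv = trace.derivative()[mask]
    if np.ptp(dv) < FLAT_EPS:
        return MarkerResult(float("nan"), False, "flat")
    t = trace.times[mask]
    return MarkerResult(float(t[int(np.argmax(dv))]), True, "ok")


def compute_ari(at: MarkerResult | float, rt: MarkerResult | float) -> MarkerResult:
    """ARI = RT - AT; invalid when either marker is invalid or RT <= AT."""
    at_t = at.time_ms if isinstance(at, MarkerResult) else float(at)
    rt_t = rt.time_ms if isinstance(rt, MarkerResult) else float(rt)
    if isinstance(at, MarkerResult) and not at.valid:
        return MarkerResult(float("nan"), False, "invalid_at")
    if isinstance(rt, MarkerResult) and not rt.valid:
        return MarkerResult(float("nan"), False, "invalid_rt")
    if not (np.isfinite(at_t) and np.isfinite(rt_t)):
        return MarkerResult(float("nan"), False, "invalid_marker")
    ari = rt_t - at_t
    if ari <= 0:
        return MarkerResult(float("nan"), False, "negative_ari")
    return MarkerResult(float(ari), True, "ok")


@dataclass
class MarkerMap:
    """Per-site AT/RT/ARI with validity flags."""

    site_id: np.ndarray
    at: np.ndarray
    rt: np.ndarray
    ari: np.ndarray
    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.site_id)
        for name in ("at", "rt", "ari", "valid", "reason"):
            if len(getattr(self, name)) != n:
                raise ValueError("all marker columns must share one length")

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(*(np.asarray(getattr(self, f))[mask] for f in ("site_id", "at", "rt", "ari", "valid", "reason")))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "AT_ms": self.at,
                "RT_ms": self.rt,
                "ARI_ms": self.ari,
                "valid": self.valid,
                "reason": self.reason,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_arrays(cls, site_id, at, rt, valid=None, reason=None) -> "MarkerMap":
        site_id = np.asarray(site_id)
        at = np.asarray(at, dtype=float)
        rt = np.asarray(rt, dtype=float)
        ari = rt - at
        if valid is None:
            valid = np.isfinite(at) & np.isfinite(rt) & (ari > 0)
        valid = np.asarray(valid, dtype=bool)
        if reason is None:
            reason = np.where(valid, "ok", "invalid")
        return cls(site_id, at, rt, ari, valid, np.asarray(reason, dtype=object))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerMap":
        df = pd.read_csv(path)
        return cls(
            df["site_id"].to_numpy(),
            df["AT_ms"].to_numpy(float),
            df["RT_ms"].to_numpy(float),
            df["ARI_ms"].to_numpy(float),
            df["valid"].to_numpy(bool),
            df["reason"].to_numpy(object),
        )


def mark_all(signals: SignalMatrix, windows: BeatWindows) -> MarkerMap:
    """Detect AT, RT, and ARI on every trace of a signal matrix.

    Per-site failures are flagged, never fatal; an empty matrix yields an
    empty map.
    """
    n = signals.n_sites
    at = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    ari = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    reason = np.full(n, "ok", dtype=object)
    for i in range(n):
        tr = signals.trace(i)
        r_at = detect_at(tr, windows.qrs)
        r_rt = detect_rt(tr, windows.twave)
        r_ari = compute_ari(r_at, r_rt)
        at[i], rt[i], ari[i] = r_at.time_ms, r_rt.time_ms, r_ari.time_ms
        valid[i] = r_ari.valid
        reason[i] = r_ari.reason if not r_ari.valid else "ok"
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("mark_all: %d/%d sites flagged invalid", n_invalid, n)
    return MarkerMap(signals.site_ids.copy(), at, rt, ari, valid, reason)


def windows_from_timing(
    at: np.ndarray,
    rt: np.ndarray,
    beat_end_ms: float,
    at_pad: tuple[float, float] = (10.0, 30.0),
    rt_pad: float = 30.0,
    guard_end_ms: float = 20.0,
) -> BeatWindows:
    """Windows from prior (e.g., ground-truth) timing maps.

    QRS: [min(AT) - at_pad[0], max(AT) + at_pad[1]]; T-wave: from
    max(QRS end, min(RT) - rt_pad) to ``beat_end_ms - guard_end_ms``.
    """
    at = np.asarray(at, dtype=float)
    rt = np.asarray(rt, dtype=float)
    qrs = (max(0.0, float(at.min()) - at_pad[0]), float(at.max()) + at_pad[1])
    tw_start = max(qrs[1], float(rt.min()) - rt_pad)
    tw_end = beat_end_ms - guard_end_ms
    if tw_end <= tw_start:
        raise ValueError("beat too short for the requested T-wave window")
    return BeatWindows(qrs=qrs, twave=(tw_start, tw_end))


def auto_windows(
    signals: SignalMatrix,
    guard_start_ms: float = 10.0,
    guard_end_ms: float = 20.0,
    min_peak_separation_ms: float = 60.0,
) -> BeatWindows:
    """Blind QRS/T-wave split from the spatial-mean absolute derivative.

    The mean over sites of |dV/dt| shows two activity bursts — the sharp QRS
    and the slower T-wave.  The split point is the minimum of that profile
    between the two bursts; the first ``guard_start_ms`` (pacing artifact) and
    last ``guard_end_ms`` of the beat are excluded from the search.
    """
    t = signals.times
    dv = np.gradient(signals.data, signals.dt, axis=1)
    profile = np.abs(dv).mean(axis=0)
    usable = (t >= signals.t0 + guard_start_ms) & (t <= t[-1] - guard_end_ms)
    if usable.sum() < 5:
        raise ValueError("beat too short for automatic windowing")
    idx = np.flatnonzero(usable)
    i_q = idx[int(np.argmax(profile[idx]))]
    late = idx[t[idx] >= t[i_q] + min_peak_separation_ms]
    if late.size == 0:
        raise ValueError("no T-wave activity found after the QRS")
    i_t = late[int(np.argmax(profile[late]))]
    between = np.arange(i_q, i_t + 1)
    i_split = between[int(np.argmin(profile[between]))]
    t_split = float(t[i_split])
    qrs = (float(signals.t0) + 0.0 if guard_start_ms == 0 else float(signals.t0) + guard_start_ms, t_split)
    logger.info("auto windows: QRS=%s, T-wave=%s", qrs, (t_split, float(t[-1]) - guard_end_ms))
    return BeatWindows(qrs=(qrs[0], t_split), twave=(t_split, float(t[-1]) - guard_end_ms))
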