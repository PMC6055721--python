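"""Uniformly sampled voltage traces and multichannel signal matrices.

Signals are stimulus-aligned: time is measured in milliseconds from the pacing
stimulus, voltages in millivolts unless the ``units`` metadata says otherwise.
The default sampling rate is 1 kHz, matching epicardial sock recordings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SignalTrace", "SignalMatrix"]

_GRID_RTOL = 1e-9


def _check_uniform(times: np.ndarray) -> float:
    """Return the (positive) step of a uniform grid or raise ``ValueError``."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 samples")
    steps = np.diff(times)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * abs(dt)):
        raise ValueError("time grid must be uniformly increasing")
    return float(dt)


@dataclass
class SignalTrace:
    """A single uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (T,)
        Voltage samples (mV by default).
    fs : float
        Sampling frequency in Hz (default 1000).
    t0 : float
        Time of the first sample relative to the stimulus, in ms.
    units : str
        Voltage units, metadata only.
    """

    samples: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trace needs a 1-D array of at least 2 samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def dt(self) -> float:
        """Sample step in ms."""
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms from the stimulus."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    def derivative(self) -> np.ndarray:
        """First time derivative (mV/ms), central differences with one-sided stencils at the ends."""
        return np.gradient(self.samples, self.dt)

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of samples with start_ms <= t <= end_ms."""
        t = self.times
        return (t >= start_ms) & (t <= end_ms)


@dataclass
class SignalMatrix:
    """A stack of traces (sites x samples) on a shared time grid."""

    data: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0
    units: str = "mV"
    site_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("signal matrix must be 2-D (sites x samples)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.site_ids is None:
            self.site_ids = np.arange(self.data.shape[0])
        else:
            self.site_ids = np.asarray(self.site_ids)
            if self.site_ids.shape != (self.data.shape[0],):
                raise ValueError("site_ids must have one entry per row")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    def trace(self, i: int) -> SignalTrace:
        """Row ``i`` as a :class:`SignalTrace`."""
        return SignalTrace(self.data[i], fs=self.fs, t0=self.t0, units=self.units)

    def same_grid(self, other: "SignalMatrix | SignalTrace") -> bool:
        n = other.samples.size if isinstance(other, SignalTrace) else other.n_samples
        return (
            np.isclose(self.fs, other.fs)
            and np.isclose(self.t0, other.t0)
            and self.n_samples == n
        )

    def select(self, mask: np.ndarray) -> "SignalMatrix":
        """Subset of sites given a boolean mask or index array."""
        return SignalMatrix(self.data[mask], fs=self.fs, t0=self.t0, units=self.units, site_ids=self.site_ids[mask])

    # -- plain-text serialization ------------------------------------------------
    def to_text(self, path: str | Path) -> None:
        """Write as delimited text, one row per site, with a metadata header line."""
        header = f"fs={self.fs:g} t0={self.t0:g} units={self.units} sites=" + ",".join(str(s) for s in self.site_ids)
        np.savetxt(path, self.data, header=header)

    @classmethod
    def from_text(cls, path: str | Path) -> "SignalMatrix":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        meta = dict(re.findall(r"(\w+)=(\S+)", first)) if first.startswith("#") else {}
        data = np.loadtxt(path)
        if data.ndim == 1:
            data = data[None, :]
        site_ids = None
        if "sites" in meta:
            site_ids = np.array([int(s) for s in meta["sites"].split(",")])
        return cls(
            data,
            fs=float(meta.get("fs", 1000.0)),
            t0=float(meta.get("t0", 0.0)),
            units=meta.get("units", "mV"),
            site_ids=site_ids,
        )


def check_uniform_grid(times: np.ndarray) -> float:
    """Public alias used by the model layer."""
    return _check_uniform(times)
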