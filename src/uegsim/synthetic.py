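"""Synthetic epicardial sock-mapping datasets with known ground truth.

The generator emulates the acquisition the validation pipeline expects:
~240 electrodes on a two-ventricle epicardial surface (abstracted as a
truncated ellipsoid), an S1 drive train of 30-50 paced beats at a fixed cycle
length between 350 and 600 ms, a spatially smooth activation spread from the
pacing electrode, repolarization equal to activation plus a spatially varying
action-potential duration (APD) with an apex-to-base gradient, and realistic
nuisances: beat-to-beat timing jitter, band-limited additive noise, slow
baseline wander, a brief pacing artifact, and a few deliberately corrupted
channels that must be caught by the quality-control filters.

The pseudo-recorded electrograms are intentionally *not* the simple model
itself: each site's AP steepness parameters are perturbed, so the recorded
and simulated morphologies agree well but not perfectly, as with real tissue.
Setting every noise/jitter amplitude to zero collapses the generator onto the
simple model exactly, which several tests exploit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.special import expit

from .markers import MarkerMap
from .model import APParams
from .signals import SignalMatrix

__all__ = [
    "GeneratorConfig",
    "SockDataset",
    "gen_geometry",
    "gen_timing_fields",
    "gen_pseudo_recorded",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic sock generator.

    Defaults describe a clean paced acquisition: 240 sites, a 30-beat S1 train,
    apex pacing at 1 mm/ms conduction velocity (activation spread of roughly
    60-120 ms across the sock), an APD near ``120 + 0.22*CL`` ms shortening
    from apex to base, millivolt-scale noise against ~25 mV QRS deflections.
    """

    n_sites: int = 240
    cycle_length: float = 600.0
    n_beats: int = 30
    fs: float = 1000.0
    pacing_site: int | None = None  # None -> apex-most electrode
    conduction_velocity: float = 1.0  # mm/ms
    activation_delay: float = 20.0  # ms, stimulus-to-first-activation latency
    apd_base: float | None = None  # ms; None -> 120 + 0.22 * cycle_length
    apd_gradient: float = -30.0  # ms apex-to-base change
    spatial_noise_sd: float = 3.0  # ms, smooth field noise on AT and APD
    spatial_noise_scale: float = 15.0  # mm, correlation length of field noise
    beat_jitter_sd: float = 0.5  # ms, per-beat timing jitter (stimulus-locked pacing is very stable)
    additive_noise_sd: float = 0.3  # mV, band-limited measurement noise
    baseline_wander_amp: float = 1.0  # mV
    baseline_wander_freq: float = 0.3  # Hz
    stim_artifact_amp: float = 8.0  # mV, 2 ms biphasic pacing artifact
    ap_shape_jitter: float = 0.15  # fractional per-site perturbation of the betas
    n_corrupt_channels: int = 8  # half alternans-like, half broadband interference
    lead_in_ms: float = 100.0
    alpha: float = 0.25
    beta_at: float = 0.4
    beta_rt: float = 0.035
    # ellipsoid semi-axes (mm) and basal truncation fraction of the long axis
    semi_axes: tuple[float, float, float] = (35.0, 35.0, 55.0)
    base_cut: float = 0.45

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        for name in ("spatial_noise_sd", "beat_jitter_sd", "additive_noise_sd", "baseline_wander_amp", "ap_shape_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 350.0 <= self.cycle_length <= 600.0:
            raise ValueError("cycle_length must lie in [350, 600] ms")
        if not 2 <= self.n_beats <= 100:
            raise ValueError("n_beats out of range")

    @property
    def apd_base_ms(self) -> float:
        return self.apd_base if self.apd_base is not None else 120.0 + 0.22 * self.cycle_length

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        d = json.loads(Path(path).read_text())
        if "semi_axes" in d:
            d["semi_axes"] = tuple(d["semi_axes"])
        return cls(**d)


@dataclass
class SockDataset:
    """A complete synthetic acquisition with its ground truth."""

    geometry: np.ndarray  # (n_sites, 3) positions, mm
    truth: MarkerMap  # generating tau_AT / tau_RT per site
    raw: SignalMatrix  # continuous record, sites x samples
    beats: np.ndarray  # (n_sites, n_beats, beat_samples) as written into `raw`
    stim_times: np.ndarray  # ms, absolute record time
    corrupt_channels: dict[str, np.ndarray]  # "alternans" and "noise" site indices
    config: GeneratorConfig
    seed: int

    @property
    def n_sites(self) -> int:
        return self.geometry.shape[0]

    def export(self, outdir: str | Path) -> None:
        """Write geometry, truth, raw signals, stimulus times, and config as plain text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"site_id": np.arange(self.n_sites), "x_mm": self.geometry[:, 0], "y_mm": self.geometry[:, 1], "z_mm": self.geometry[:, 2]}
        ).to_csv(outdir / "geometry.csv", index=False)
        self.truth.to_csv(outdir / "truth_markers.csv")
        self.raw.to_text(outdir / "raw_signals.txt")
        pd.DataFrame({"stim_ms": self.stim_times}).to_csv(outdir / "stim_times.csv", index=False)
        self.config.to_json(outdir / "generator_config.json")


def _fibonacci_ellipsoid(n: int, semi_axes: tuple[float, float, float], base_cut: float) -> np.ndarray:
    """Quasi-uniform points on a basally truncated ellipsoid (apex at -c)."""
    a, b, c = semi_axes
    z_cut = base_cut * c
    pts = []
    n_full = int(np.ceil(n / max(1e-6, (1.0 + base_cut) / 2.0)))  # truncation keeps ~(1+cut)/2 of the sphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    while len(pts) < n:
        pts = []
        for k in range(n_full):
            zs = 1.0 - 2.0 * (k + 0.5) / n_full  # unit-sphere z from south (apex) upward
            r = np.sqrt(max(0.0, 1.0 - zs * zs))
            th = golden * k
            x, y, z = a * r * np.cos(th), b * r * np.sin(th), c * zs
            if z <= z_cut:
                pts.append((x, y, z))
        n_full = int(n_full * 1.2) + 1
    return np.array(pts[:n])


def gen_geometry(cfg: GeneratorConfig, seed: int = 0) -> np.ndarray:
    """Electrode positions (mm) on the truncated-ellipsoid sock surface.

    The layout is a deterministic Fibonacci spiral; the seed only adds a small
    tangential jitter so distinct socks are not sample-identical.
    """
    pts = _fibonacci_ellipsoid(cfg.n_sites, cfg.semi_axes, cfg.base_cut)
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 0.5, size=pts.shape)
    return pts + jitter


def _smooth_field(geometry: np.ndarray, rng: np.random.Generator, sd: float, length_scale: float) -> np.ndarray:
    """Spatially correlated zero-mean field with pointwise standard deviation ``sd``."""
    n = geometry.shape[0]
    if sd == 0:
        return np.zeros(n)
    z = rng.normal(size=n)
    d2 = ((geometry[:, None, :] - geometry[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * length_scale**2))
    f = w @ z
    f = f - f.mean()
    s = f.std()
    return f * (sd / s) if s > 0 else np.zeros(n)


def gen_timing_fields(geometry: np.ndarray, cfg: GeneratorConfig, seed: int = 0) -> MarkerMap:
    """Ground-truth activation/repolarization fields.

    Activation spreads from the pacing electrode at the configured conduction
    velocity (straight-line distances on the sock surface points); APD has an
    apex-to-base gradient; both fields carry smooth correlated noise.  Raises
    when the configuration pushes repolarization past the beat window.
    """
    rng = np.random.default_rng(seed)
    pacing = cfg.pacing_site if cfg.pacing_site is not None else int(np.argmin(geometry[:, 2]))
    dist = np.linalg.norm(geometry - geometry[pacing], axis=1)
    at = cfg.activation_delay + dist / cfg.conduction_velocity
    at = at + _smooth_field(geometry, rng, cfg.spatial_noise_sd, cfg.spatial_noise_scale)
    z = geometry[:, 2]
    frac = (z - z.min()) / max(1e-9, z.max() - z.min())
    apd = cfg.apd_base_ms + cfg.apd_gradient * frac
    apd = apd + _smooth_field(geometry, rng, cfg.spatial_noise_sd, cfg.spatial_noise_scale)
    rt = at + apd
    if np.any(rt >= cfg.cycle_length):
        raise ValueError("configuration places repolarization beyond the beat window")
    if np.any(apd <= 0):
        raise ValueError("configuration yields nonpositive APD")
    return MarkerMap.from_arrays(np.arange(geometry.shape[0]), at, rt)


def _bandlimited_noise(rng: np.random.Generator, n: int, sd: float, fs: float, cutoff_hz: float = 100.0) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(size=n)
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    x = filtfilt(b, a, white)
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def gen_pseudo_recorded(
    truth: MarkerMap,
    cfg: GeneratorConfig,
    seed: int = 0,
) -> tuple[SignalMatrix, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Multi-beat noisy pseudo-recordings for a ground-truth timing map.

    Each beat is an electrogram from the simple-model family, but with
    per-site perturbed steepness parameters and per-beat timing jitter, plus
    additive band-limited noise, baseline wander, and a 2 ms pacing artifact.
    ``cfg.n_corrupt_channels`` channels are corrupted: alternans-like channels
    alternate between two morphologies (tripping the beat-stability filter)
    and interference channels carry a strong stimulus-locked 60 Hz component
    (tripping the spectral-SNR filter).

    Returns ``(raw, beats, stim_times, corrupt_channels)`` where ``beats`` is
    the (n_sites, n_beats, beat_samples) array exactly as written into the
    continuous record ``raw``.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_sites
    at = np.asarray(truth.at, dtype=float)
    rt = np.asarray(truth.rt, dtype=float)
    fs, cl = cfg.fs, cfg.cycle_length
    dt = 1000.0 / fs
    beat_samples = int(round(cl * fs / 1000.0))
    t_beat = np.arange(beat_samples) * dt

    # per-site AP shape perturbations (position-dependence the simple model lacks)
    b_at = cfg.beta_at * np.exp(rng.normal(0.0, cfg.ap_shape_jitter, n)) if cfg.ap_shape_jitter > 0 else np.full(n, cfg.beta_at)
    b_rt = cfg.beta_rt * np.exp(rng.normal(0.0, cfg.ap_shape_jitter, n)) if cfg.ap_shape_jitter > 0 else np.full(n, cfg.beta_rt)
    params = APParams(beta_at=cfg.beta_at, beta_rt=cfg.beta_rt)

    # corrupt-channel assignment
    n_corrupt = min(cfg.n_corrupt_channels, n)
    corrupt = rng.choice(n, size=n_corrupt, replace=False) if n_corrupt else np.array([], dtype=int)
    alternans_idx = corrupt[: n_corrupt // 2]
    noise_idx = corrupt[n_corrupt // 2 :]

    total = int(round(cfg.lead_in_ms * fs / 1000.0)) + cfg.n_beats * beat_samples + int(round(50 * fs / 1000.0))
    stim_times = cfg.lead_in_ms + cl * np.arange(cfg.n_beats)
    raw = np.zeros((n, total))
    t_abs = np.arange(total) * dt

    # record-wide nuisances
    for i in range(n):
        raw[i] += _bandlimited_noise(rng, total, cfg.additive_noise_sd, fs)
        if cfg.baseline_wander_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            raw[i] += cfg.baseline_wander_amp * np.sin(2 * np.pi * cfg.baseline_wander_freq * t_abs / 1000.0 + phase)

    artifact = np.zeros(beat_samples)
    n_art = int(round(2.0 * fs / 1000.0))
    if n_art >= 2 and cfg.stim_artifact_amp > 0:
        artifact[:n_art] = cfg.stim_artifact_amp * np.array([1.0, -1.0] + [0.0] * (n_art - 2))[:n_art]

    sin60 = np.sin(2 * np.pi * 60.0 * t_beat / 1000.0)

    b_rt_c = np.minimum(b_rt, 0.99 * b_at)  # recovery must stay slower than activation

    def ueg_beat(at_b: np.ndarray, rt_b: np.ndarray) -> np.ndarray:
        """One beat of pseudo-recorded UEGs with per-site shape parameters."""
        act = expit(b_at[:, None] * (t_beat[None, :] - at_b[:, None]))
        rec = 1.0 - expit(b_rt_c[:, None] * (t_beat[None, :] - rt_b[:, None]))
        aps = params.A * act * rec - params.v_rest
        remote = aps.mean(axis=0)
        return -cfg.alpha * (aps - remote[None, :])

    # alternate morphology for alternans channels: shifted activation, inverted T drift
    alt_at = at.copy()
    alt_rt = rt.copy()
    if alternans_idx.size:
        alt_at[alternans_idx] = at[alternans_idx] + 40.0
        alt_rt[alternans_idx] = rt[alternans_idx] - 60.0
        alt_rt[alternans_idx] = np.maximum(alt_rt[alternans_idx], alt_at[alternans_idx] + 60.0)

    for k in range(cfg.n_beats):
        jit = rng.normal(0.0, cfg.beat_jitter_sd, n) if cfg.beat_jitter_sd > 0 else np.zeros(n)
        beat = ueg_beat(at + jit, rt + jit)
        if alternans_idx.size and k % 2 == 1:
            beat_alt = ueg_beat(alt_at + jit, alt_rt + jit)
            beat[alternans_idx] = beat_alt[alternans_idx]
        if noise_idx.size:
            beat[noise_idx] += 30.0 * sin60[None, :]
        beat += artifact[None, :]
        i0 = int(round(stim_times[k] * fs / 1000.0))
        raw[:, i0 : i0 + beat_samples] += beat

    beats = np.empty((n, cfg.n_beats, beat_samples))
    for k in range(cfg.n_beats):
        i0 = int(round(stim_times[k] * fs / 1000.0))
        beats[:, k, :] = raw[:, i0 : i0 + beat_samples]

    raw_mat = SignalMatrix(raw, fs=fs, t0=0.0)
    return raw_mat, beats, stim_times, {"alternans": alternans_idx, "noise": noise_idx}


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> SockDataset:
    """Full synthetic acquisition: geometry, truth fields, and raw recordings.

    Bit-reproducible from ``(cfg, seed)``; the sub-stage seeds are derived from
    ``seed`` so geometry, timing, and signals use independent streams.
    """
    ss = np.random.SeedSequence(seed)
    s_geo, s_tim, s_sig = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    geometry = gen_geometry(cfg, seed=s_geo)
    truth = gen_timing_fields(geometry, cfg, seed=s_tim)
    raw, beats, stim_times, corrupt = gen_pseudo_recorded(truth, cfg, seed=s_sig)
    return SockDataset(
        geometry=geometry,
        truth=truth,
        raw=raw,
        beats=beats,
        stim_times=stim_times,
        corrupt_channels=corrupt,
        config=cfg,
        seed=seed,
    )


def clean_config(cfg: GeneratorConfig | None = None) -> GeneratorConfig:
    """A copy of ``cfg`` with every nuisance switched off (generator collapses onto the model)."""
    base = cfg or GeneratorConfig()
    # spatial field noise is part of the ground truth, not a nuisance, and is kept
    return replace(
        base,
        beat_jitter_sd=0.0,
        additive_noise_sd=0.0,
        baseline_wander_amp=0.0,
        stim_artifact_amp=0.0,
        ap_shape_jitter=0.0,
        n_corrupt_channels=0,
    )
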