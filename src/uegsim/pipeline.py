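"""End-to-end validation pipeline.

Stages, mirroring the sock-mapping validation workflow: load or generate a
dataset -> segment the drive train into beats -> quality control (stability +
SNR) -> signal averaging -> AT/RT marker detection -> simulate electrograms
from the measured markers (grid-searching the steepness pair) -> morphology
correlations and timing/area statistics -> a per-cycle-length summary table
whose rows parallel the headline validation table (recorded "R" side vs model
"M" side).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .betasearch import BetaGrid, grid_search_beta
from .markers import MarkerMap, auto_windows, mark_all, windows_from_timing
from .model import APParams, ConductivityScaling, simulate_from_markers
from .morphology import morphology_compare, pearson_cc, timing_area_maps
from .qc import QCConfig, run_qc, segment_beats
from .signals import SignalMatrix
from .synthetic import GeneratorConfig, SockDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "ValidationSummary", "run_validation", "load_dataset"]


class StageError(RuntimeError):
    """A pipeline stage left zero usable sites."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full validation run.

    Exactly one input mode: either ``generator`` (synthesize a dataset per
    cycle length) or ``input_dir`` (a directory written by
    :meth:`uegsim.synthetic.SockDataset.export`).
    """

    cycle_lengths: tuple[float, ...] = (600.0,)
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    input_dir: str | Path | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    grid: BetaGrid = field(default_factory=BetaGrid)
    scaling: ConductivityScaling = field(default_factory=ConductivityScaling)
    windows_policy: str = "auto"  # "auto" (blind split) or "priors" (truth/marker-informed)
    outdir: str | Path | None = None
    seed: int = 0
    run_grid_search: bool = True
    fixed_beta: tuple[float, float] | None = None  # used when run_grid_search is False

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("exactly one of generator / input_dir must be set")
        if self.windows_policy not in ("auto", "priors"):
            raise ValueError("windows_policy must be 'auto' or 'priors'")


def load_dataset(input_dir: str | Path) -> SockDataset:
    """Load a dataset previously written by :meth:`SockDataset.export`."""
    d = Path(input_dir)
    cfg = GeneratorConfig.from_json(d / "generator_config.json")
    raw = SignalMatrix.from_text(d / "raw_signals.txt")
    stim = pd.read_csv(d / "stim_times.csv")["stim_ms"].to_numpy(float)
    truth = MarkerMap.from_csv(d / "truth_markers.csv")
    geom = pd.read_csv(d / "geometry.csv")[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    beat_samples = int(round(cfg.cycle_length * raw.fs / 1000.0))
    beats = np.stack(
        [raw.data[:, int(round(s * raw.fs / 1000.0)) : int(round(s * raw.fs / 1000.0)) + beat_samples] for s in stim],
        axis=1,
    )
    return SockDataset(
        geometry=geom, truth=truth, raw=raw, beats=beats, stim_times=stim,
        corrupt_channels={"alternans": np.array([], int), "noise": np.array([], int)},
        config=cfg, seed=-1,
    )


def _cl_seed(seed: int, cycle_length: float) -> int:
    return int(np.random.SeedSequence([seed, int(cycle_length)]).generate_state(1)[0] % (2**31))


#: summary row order, paralleling the validation table
SUMMARY_ROWS = [
    "n_kept",
    "n_valid",
    "delta_AT_median", "delta_AT_mad", "cc_AT",
    "delta_RT_median", "delta_RT_mad", "cc_RT",
    "delta_ARI_median", "delta_ARI_mad", "cc_ARI",
    "cc_UEG_median", "cc_UEG_mad",
    "cc_QRS_median", "cc_QRS_mad",
    "cc_TW_median", "cc_TW_mad",
    "cc_QRSa", "cc_TWa",
    "cc_AT_QRSa_R", "cc_AT_QRSa_M",
    "cc_RT_TWa_R", "cc_RT_TWa_M",
    "beta_AT", "beta_RT",
]


@dataclass
class ValidationSummary:
    """Per-cycle-length summary metrics (rows) by cycle length (columns)."""

    table: pd.DataFrame
    details: dict[float, dict]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.10g")


def _analyze_cycle_length(dataset: SockDataset, config: RunConfig, cl: float, outdir: Path | None) -> dict:
    qc_cfg = config.qc
    stacks = segment_beats(dataset.raw, dataset.stim_times, cl, qc_cfg.n_discard_initial_beats)
    qcr = run_qc(stacks, qc_cfg, site_ids=np.arange(dataset.n_sites))
    averaged = qcr.averaged
    if averaged is None or averaged.n_sites == 0:
        raise StageError("qc", "no site survived quality control")

    kept_ids = averaged.site_ids
    if config.windows_policy == "priors":
        truth_at = np.asarray(dataset.truth.at, float)[kept_ids]
        truth_rt = np.asarray(dataset.truth.rt, float)[kept_ids]
        windows = windows_from_timing(truth_at, truth_rt, beat_end_ms=cl)
    else:
        windows = auto_windows(averaged)

    rec_markers = mark_all(averaged, windows)
    valid = np.asarray(rec_markers.valid, bool)
    if valid.sum() < 10:
        raise StageError("markers", "fewer than 10 valid marker sites")

    if config.run_grid_search:
        search = grid_search_beta(averaged, rec_markers, config.grid, config.scaling)
        beta_at, beta_rt = search.beta_at, search.beta_rt
    else:
        if config.fixed_beta is None:
            raise StageError("beta", "run_grid_search=False requires fixed_beta")
        beta_at, beta_rt = config.fixed_beta
        search = None

    at = np.asarray(rec_markers.at, float)[valid]
    rt = np.asarray(rec_markers.rt, float)[valid]
    rec_valid = averaged.select(valid)
    params = APParams(beta_at=beta_at, beta_rt=beta_rt)
    sim = simulate_from_markers(at, rt, params=params, scaling=config.scaling, cycle_length=cl, fs=averaged.fs,
                                site_ids=rec_valid.site_ids)
    model_markers = mark_all(sim, windows)
    morpho = morphology_compare(rec_valid, sim, windows)

    m_ok = np.asarray(model_markers.valid, bool)
    d_at = at[m_ok] - np.asarray(model_markers.at, float)[m_ok]
    d_rt = rt[m_ok] - np.asarray(model_markers.rt, float)[m_ok]
    d_ari = (rt - at)[m_ok] - np.asarray(model_markers.ari, float)[m_ok]

    def med_mad(x: np.ndarray) -> tuple[float, float]:
        med = float(np.median(x))
        return med, float(np.median(np.abs(x - med)))

    ps = morpho.per_site
    cc_at_qrsa_r, cc_rt_twa_r = timing_area_maps(at, rt, ps["qrs_area_recorded"], ps["twave_area_recorded"])
    cc_at_qrsa_m, cc_rt_twa_m = timing_area_maps(
        np.asarray(model_markers.at, float), np.asarray(model_markers.rt, float),
        ps["qrs_area_simulated"], ps["twave_area_simulated"],
    )

    row: dict[str, float] = {}
    row["n_kept"] = int(averaged.n_sites)
    row["n_valid"] = int(valid.sum())
    row["delta_AT_median"], row["delta_AT_mad"] = med_mad(d_at)
    row["cc_AT"] = pearson_cc(at[m_ok], np.asarray(model_markers.at, float)[m_ok])
    row["delta_RT_median"], row["delta_RT_mad"] = med_mad(d_rt)
    row["cc_RT"] = pearson_cc(rt[m_ok], np.asarray(model_markers.rt, float)[m_ok])
    row["delta_ARI_median"], row["delta_ARI_mad"] = med_mad(d_ari)
    row["cc_ARI"] = pearson_cc((rt - at)[m_ok], np.asarray(model_markers.ari, float)[m_ok])
    for key, col in (("cc_UEG", "cc_whole"), ("cc_QRS", "cc_qrs"), ("cc_TW", "cc_twave")):
        s = morpho.summaries[col]
        row[f"{key}_median"], row[f"{key}_mad"] = s.median, s.mad
    row["cc_QRSa"] = morpho.cc_qrs_area
    row["cc_TWa"] = morpho.cc_twave_area
    row["cc_AT_QRSa_R"] = cc_at_qrsa_r
    row["cc_AT_QRSa_M"] = cc_at_qrsa_m
    row["cc_RT_TWa_R"] = cc_rt_twa_r
    row["cc_RT_TWa_M"] = cc_rt_twa_m
    row["beta_AT"] = beta_at
    row["beta_RT"] = beta_rt

    if outdir is not None:
        cl_dir = outdir / f"cl_{int(cl)}"
        cl_dir.mkdir(parents=True, exist_ok=True)
        qcr.to_csv(cl_dir / "qc_report.csv")
        rec_markers.to_csv(cl_dir / "markers.csv")
        if search is not None:
            search.to_csv(cl_dir / "beta_scores.csv")
        morpho.to_csv(cl_dir / "morphology.csv")
        (cl_dir / "summary.json").write_text(json.dumps(row, indent=1))

    return {
        "row": row,
        "qc": qcr,
        "windows": windows,
        "recorded_markers": rec_markers,
        "model_markers": model_markers,
        "morphology": morpho,
        "beta": (beta_at, beta_rt),
        "beta_table": None if search is None else search.table,
        "recorded": rec_valid,
        "simulated": sim,
    }


def run_validation(config: RunConfig) -> ValidationSummary:
    """Run the full pipeline for every configured cycle length.

    Deterministic in ``(config, seed)``: per-cycle-length dataset seeds are
    derived from the run seed, and every later stage is seed-free.
    """
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    columns: dict[float, dict] = {}
    details: dict[float, dict] = {}
    for cl in config.cycle_lengths:
        if config.generator is not None:
            gen_cfg = replace(config.generator, cycle_length=float(cl))
            dataset = generate_dataset(gen_cfg, seed=_cl_seed(config.seed, cl))
        else:
            dataset = load_dataset(config.input_dir)
            if not np.isclose(dataset.config.cycle_length, cl):
                raise StageError("load", f"dataset cycle length {dataset.config.cycle_length} != requested {cl}")
        logger.info("cycle length %g ms: %d sites, %d beats", cl, dataset.n_sites, dataset.config.n_beats)
        detail = _analyze_cycle_length(dataset, config, float(cl), outdir)
        columns[float(cl)] = detail["row"]
        details[float(cl)] = detail

    table = pd.DataFrame({cl: columns[cl] for cl in columns}).reindex(SUMMARY_ROWS)
    summary = ValidationSummary(table=table, details=details)
    if outdir is not None:
        summary.to_csv(outdir / "summary.csv")
        cfg_dict = {
            "cycle_lengths": list(config.cycle_lengths),
            "seed": config.seed,
            "windows_policy": config.windows_policy,
            "qc": asdict(config.qc),
            "grid": asdict(config.grid),
            "alpha": config.scaling.alpha,
            "generator": None if config.generator is None else asdict(config.generator),
            "input_dir": None if config.input_dir is None else str(config.input_dir),
        }
        blob = json.dumps(cfg_dict, sort_keys=True, default=str)
        log = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "uegsim_version": __import__("uegsim").__version__,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return summary
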