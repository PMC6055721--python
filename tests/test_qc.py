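"""Beat segmentation, stability/SNR filters, signal averaging."""

import numpy as np
import pytest

from uegsim import (
    BeatStack,
    QCConfig,
    SignalMatrix,
    generate_dataset,
    segment_beats,
    signal_average,
    spectral_snr,
    stability_filter,
)
from uegsim.qc import run_qc
from uegsim.signals import SignalTrace


@pytest.fixture(scope="module")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg, seed=11)


class TestSegmentation:
    def test_beat_count_and_length(self):
        rng = np.random.default_rng(0)
        fs, cl, n_beats = 1000.0, 600.0, 30
        stim = 100.0 + cl * np.arange(n_beats)
        raw = SignalMatrix(rng.normal(size=(3, int(100 + n_beats * cl + 50))), fs=fs)
        stacks = segment_beats(raw, stim, cl)
        assert len(stacks) == 3
        assert stacks[0].beats.shape == (30, 600)

    def test_empty_stimulus_list_rejected(self):
        raw = SignalMatrix(np.zeros((2, 1000)))
        with pytest.raises(ValueError):
            segment_beats(raw, np.array([]), 600.0)

    def test_roundtrip_against_generator(self, small_dataset, small_cfg):
        """Extracted beats match the generator's own beat array sample-for-sample."""
        stacks = segment_beats(small_dataset.raw, small_dataset.stim_times, small_cfg.cycle_length, 0)
        for i in (0, 17, 59):
            assert np.array_equal(stacks[i].beats, small_dataset.beats[i])

    def test_initial_beat_discard(self, small_dataset, small_cfg):
        stacks = segment_beats(small_dataset.raw, small_dataset.stim_times, small_cfg.cycle_length, 3)
        assert stacks[0].n_beats == small_cfg.n_beats - 3
        assert np.array_equal(stacks[0].beats[0], small_dataset.beats[0][3])


class TestStabilityFilter:
    def test_identical_beats_keep(self):
        beat = np.sin(np.linspace(0, 6 * np.pi, 500))
        stack = BeatStack(np.tile(beat, (10, 1)), cycle_length=500.0)
        keep, cc = stability_filter(stack)
        assert keep and cc == pytest.approx(1.0)

    def test_scaled_ectopic_transient_trips_criterion(self):
        """An ectopic-shaped beat, scaled until the mean cc falls below 0.98, is rejected."""
        rng = np.random.default_rng(1)
        t = np.arange(500.0)
        beat = np.exp(-0.5 * ((t - 120) / 10.0) ** 2) - 0.4 * np.exp(-0.5 * ((t - 300) / 40.0) ** 2)
        ectopic = np.exp(-0.5 * ((t - 260) / 25.0) ** 2)
        beats = np.tile(beat, (10, 1)) + rng.normal(0, 1e-3, (10, 500))
        # brute-force the smallest scale whose admixture trips the criterion
        scale = None
        for s in np.linspace(0.1, 5.0, 50):
            trial = beats.copy()
            trial[4] = s * ectopic
            if stability_filter(BeatStack(trial, cycle_length=500.0))[1] < 0.98:
                scale = s
                break
        assert scale is not None
        beats[4] = scale * ectopic
        keep, cc = stability_filter(BeatStack(beats, cycle_length=500.0))
        assert not keep and cc < 0.98

    def test_alternating_morphologies_rejected(self):
        rng = np.random.default_rng(2)
        a = np.sin(np.linspace(0, 4 * np.pi, 400))
        b = np.cos(np.linspace(0, 7 * np.pi, 400))
        beats = np.stack([a if k % 2 == 0 else b for k in range(12)]) + rng.normal(0, 1e-6, (12, 400))
        keep, cc = stability_filter(BeatStack(beats, cycle_length=400.0))
        assert not keep

    def test_zero_variance_beat_counts_as_zero(self):
        beat = np.sin(np.linspace(0, 4 * np.pi, 300))
        beats = np.tile(beat, (5, 1))
        beats[2] = 0.0
        keep, cc = stability_filter(BeatStack(beats, cycle_length=300.0))
        assert cc == pytest.approx(4.0 / 5.0, abs=1e-6)
        assert not keep


class TestSpectralSNR:
    def test_in_band_sinusoid_kept(self):
        t = np.arange(0, 1.0, 1e-3)
        tr = SignalTrace(np.sin(2 * np.pi * 10.0 * t), fs=1000.0)
        assert spectral_snr(tr) > 10.0

    def test_noise_band_sinusoid_rejected(self):
        t = np.arange(0, 1.0, 1e-3)
        tr = SignalTrace(np.sin(2 * np.pi * 60.0 * t), fs=1000.0)
        assert spectral_snr(tr) < 0.0

    def test_white_noise_matches_band_width_ratio(self):
        """Flat PSD: SNR -> 10*log10(39/60) ~ -1.87 dB (long-sample Monte Carlo)."""
        rng = np.random.default_rng(3)
        vals = [spectral_snr(SignalTrace(rng.normal(size=20000), fs=1000.0)) for _ in range(10)]
        assert np.mean(vals) == pytest.approx(10 * np.log10(39 / 60), abs=0.4)


class TestSignalAverage:
    def test_single_beat_and_idempotence(self):
        beat = np.sin(np.linspace(0, 4 * np.pi, 400))
        one = signal_average(BeatStack(beat[None, :], cycle_length=400.0))
        assert np.array_equal(one.samples, beat)
        many = signal_average(BeatStack(np.tile(beat, (7, 1)), cycle_length=400.0))
        assert np.allclose(many.samples, beat)

    def test_noise_reduction_scales_as_sqrt_n(self):
        """Residual sd after averaging n iid-noise beats ~ sigma/sqrt(n)."""
        rng = np.random.default_rng(4)
        sigma, n = 2.0, 25
        beat = np.sin(np.linspace(0, 4 * np.pi, 2000))
        resid_sds = []
        for _ in range(30):
            beats = beat[None, :] + rng.normal(0, sigma, (n, 2000))
            avg = signal_average(BeatStack(beats, cycle_length=2000.0))
            resid_sds.append((avg.samples - beat).std())
        assert np.mean(resid_sds) == pytest.approx(sigma / np.sqrt(n), rel=0.1)


class TestRunQC:
    def test_corrupt_channels_rejected_clean_retained(self, small_dataset, small_cfg):
        stacks = segment_beats(small_dataset.raw, small_dataset.stim_times, small_cfg.cycle_length, 2)
        report = run_qc(stacks, QCConfig())
        t = report.table
        corrupt = np.concatenate(list(small_dataset.corrupt_channels.values()))
        clean = np.setdiff1d(np.arange(small_cfg.n_sites), corrupt)
        assert not t.loc[t.site_id.isin(corrupt), "kept"].any()
        assert t.loc[t.site_id.isin(clean), "kept"].mean() >= 0.95
        # each corrupt class trips the filter it was constructed to violate
        alt = small_dataset.corrupt_channels["alternans"]
        noi = small_dataset.corrupt_channels["noise"]
        assert (t.loc[t.site_id.isin(alt), "reason"] == "stability").all()
        assert (t.loc[t.site_id.isin(noi), "reason"] == "snr").all()

    def test_threshold_monotonicity(self, small_dataset, small_cfg):
        """Loosening either threshold never decreases the retained-site count."""
        stacks = segment_beats(small_dataset.raw, small_dataset.stim_times, small_cfg.cycle_length, 2)
        strict = run_qc(stacks, QCConfig()).kept_mask.sum()
        lower_cc = run_qc(stacks, QCConfig(stability_cc_min=0.9)).kept_mask.sum()
        lower_snr = run_qc(stacks, QCConfig(snr_min_db=0.0)).kept_mask.sum()
        assert lower_cc >= strict and lower_snr >= strict

    def test_decisions_are_per_site(self, small_dataset, small_cfg):
        """QC outcome for a site is unchanged when other sites are dropped."""
        stacks = segment_beats(small_dataset.raw, small_dataset.stim_times, small_cfg.cycle_length, 2)
        full = run_qc(stacks, QCConfig()).table
        part = run_qc(stacks[:10], QCConfig()).table
        assert np.array_equal(full.kept.to_numpy()[:10], part.kept.to_numpy())
        assert np.allclose(full.mean_cc.to_numpy()[:10], part.mean_cc.to_numpy()[:10])


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QCConfig(stability_cc_min=1.5)
    with pytest.raises(ValueError):
        QCConfig(signal_band=(1.0, 50.0), noise_band=(40.0, 100.0))
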