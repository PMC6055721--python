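"""Derivative-based AT/RT/ARI detection (Wyatt method)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uegsim import (
    BeatWindows,
    MarkerMap,
    SignalMatrix,
    SiteTiming,
    ap_ensemble,
    compute_ari,
    detect_at,
    detect_rt,
    mark_all,
    simulate_from_markers,
    simulate_ueg,
    windows_from_timing,
)
from uegsim.markers import auto_windows
from uegsim.signals import SignalTrace


def make_roundtrip_ueg(rng=None, n=60, cl=600.0):
    """Physiologic field: smooth activation spread, APD shortening with late activation."""
    r = np.random.default_rng(5) if rng is None else rng
    at = np.sort(r.uniform(40.0, 130.0, n))
    rt = at + 260.0 - 0.35 * (at - 40.0) + r.normal(0, 3, n)
    return at, rt, simulate_from_markers(at, rt, cycle_length=cl)


class TestDetectAT:
    def test_constructed_steepest_descent_sample(self):
        v = np.zeros(100)
        v[40:] = -1.0
        v[39] = -0.2  # single steepest drop between samples 39 and 40
        tr = SignalTrace(v, fs=1000.0, t0=0.0)
        res = detect_at(tr, (10.0, 90.0))
        assert res.valid and res.time_ms == pytest.approx(39.5, abs=0.6)

    def test_known_tau_recovered(self):
        at, rt, ueg = make_roundtrip_ueg()
        w = windows_from_timing(at, rt, 600.0)
        det = np.array([detect_at(ueg.trace(i), w.qrs).time_ms for i in range(ueg.n_sites)])
        assert np.max(np.abs(det - at)) <= 1.0

    def test_shift_equivariance(self):
        at, rt, ueg = make_roundtrip_ueg(n=12)
        tr = ueg.trace(0)
        shifted = SignalTrace(tr.samples, fs=tr.fs, t0=tr.t0 + 15.0)
        w = windows_from_timing(at, rt, 600.0)
        a0 = detect_at(tr, w.qrs).time_ms
        a1 = detect_at(shifted, (w.qrs[0] + 15.0, w.qrs[1] + 15.0)).time_ms
        assert a1 == pytest.approx(a0 + 15.0)

    def test_flat_window_flagged(self):
        tr = SignalTrace(np.zeros(200), fs=1000.0)
        res = detect_at(tr, (50.0, 150.0))
        assert not res.valid and res.reason == "flat"


class TestDetectRT:
    def test_wyatt_rule_matches_dense_grid_oracle_for_both_polarities(self):
        """The 1 kHz detection agrees with a 0.1 ms finite-difference oracle of the
        same electrogram, for positive and negative T-waves alike."""
        at, rt, coarse = make_roundtrip_ueg(n=40)
        w = windows_from_timing(at, rt, 600.0)
        dense = simulate_from_markers(at, rt, cycle_length=600.0, fs=10000.0)
        t_c, t_d = coarse.times, dense.times
        tw_c = (t_c >= w.twave[0]) & (t_c <= w.twave[1])
        tw_d = (t_d >= w.twave[0]) & (t_d <= w.twave[1])
        areas = np.trapezoid(coarse.data[:, tw_c], t_c[tw_c], axis=1)
        i_pos, i_neg = int(np.argmax(areas)), int(np.argmin(areas))
        assert areas[i_pos] > 0 > areas[i_neg]  # both polarities present
        for i in (i_pos, i_neg, 20):
            det = detect_rt(coarse.trace(i), w.twave)
            dv_dense = np.gradient(dense.data[i], 0.1)
            oracle = t_d[tw_d][np.argmax(dv_dense[tw_d])]
            assert det.valid
            assert det.time_ms == pytest.approx(oracle, abs=1.0)

    def test_measured_marker_roundtrip_is_consistent(self, timing_240, ueg_240):
        """Markers measured from electrograms, used as model input, are recovered
        from the re-simulated electrograms (the validation's marker comparison)."""
        at = np.asarray(timing_240.at, float)
        rt = np.asarray(timing_240.rt, float)
        ueg = ueg_240
        w = windows_from_timing(at, rt, 600.0)
        mm_rec = mark_all(ueg, w)
        at_r = np.asarray(mm_rec.at, float)
        rt_r = np.asarray(mm_rec.rt, float)
        sim = simulate_from_markers(at_r, rt_r, cycle_length=600.0)
        mm_sim = mark_all(sim, w)
        assert abs(np.median(at_r - np.asarray(mm_sim.at))) <= 0.5
        assert abs(np.median(rt_r - np.asarray(mm_sim.rt))) <= 1.0
        assert np.corrcoef(rt_r, np.asarray(mm_sim.rt))[0, 1] > 0.99

    def test_time_reversal_antisymmetry(self):
        """On a reversed trace the max-derivative time maps to the original
        min-derivative time in the mirrored window."""
        at, rt, ueg = make_roundtrip_ueg(n=8)
        tr = ueg.trace(3)
        rev = SignalTrace(tr.samples[::-1].copy(), fs=tr.fs, t0=0.0)
        t_end = tr.times[-1]
        # rev'(t) = -v'(t_end - t): max over [a, b] of rev' maps to min of v' over [t_end-b, t_end-a]
        a, b = 39.0, 399.0
        dv = tr.derivative()
        mask = (tr.times >= t_end - b) & (tr.times <= t_end - a)
        expected = t_end - tr.times[mask][np.argmin(dv[mask])]
        res_rev = detect_rt(rev, (a, b))
        assert res_rev.valid
        assert res_rev.time_ms == pytest.approx(expected, abs=1.0)


class TestARI:
    def test_arithmetic_and_degenerate(self):
        assert compute_ari(120.0, 340.0).time_ms == pytest.approx(220.0)
        assert not compute_ari(120.0, 120.0).valid
        assert compute_ari(120.0, 100.0).reason == "negative_ari"

    def test_markermap_ari_identity(self):
        at, rt, ueg = make_roundtrip_ueg(n=20)
        w = windows_from_timing(at, rt, 600.0)
        mm = mark_all(ueg, w)
        ok = np.asarray(mm.valid, bool)
        assert np.allclose(np.asarray(mm.ari)[ok], (np.asarray(mm.rt) - np.asarray(mm.at))[ok])


class TestMarkAll:
    def test_roundtrip_median_zero_and_cc_one(self, timing_240, ueg_240):
        at = np.asarray(timing_240.at, float)
        rt = np.asarray(timing_240.rt, float)
        w = windows_from_timing(at, rt, 600.0)
        mm = mark_all(ueg_240, w)
        assert np.asarray(mm.valid, bool).all()
        d_at = np.asarray(mm.at) - at
        assert abs(np.median(d_at)) <= 0.5
        assert np.corrcoef(at, np.asarray(mm.at))[0, 1] > 0.999

    def test_empty_matrix_gives_empty_map(self):
        mat = SignalMatrix(np.zeros((0, 600)), fs=1000.0)
        mm = mark_all(mat, BeatWindows(qrs=(10.0, 200.0), twave=(250.0, 560.0)))
        assert mm.n_sites == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(gain=st.floats(0.05, 50.0), offset=st.floats(-30.0, 30.0))
    def test_affine_voltage_invariance(self, gain, offset):
        at, rt, ueg = make_roundtrip_ueg(n=10)
        w = windows_from_timing(at, rt, 600.0)
        tr = ueg.trace(4)
        scaled = SignalTrace(gain * tr.samples + offset, fs=tr.fs, t0=tr.t0)
        assert detect_at(scaled, w.qrs).time_ms == detect_at(tr, w.qrs).time_ms
        assert detect_rt(scaled, w.twave).time_ms == detect_rt(tr, w.twave).time_ms


class TestSlowRemoteCondition:
    def test_markers_exact_where_remote_is_slow(self, params):
        """Sites whose window-local remote slope is <10% of the local peak slope
        are recovered within 1 sample (AT) / 2 ms (RT)."""
        # one site isolated in time: its neighbours' slopes are negligible there
        timings = [SiteTiming(100.0, 280.0)] * 59 + [SiteTiming(150.0, 460.0)]
        ens = ap_ensemble(np.arange(0.0, 600.0), params, timings)
        ueg = simulate_ueg(ens)
        remote_dv = np.gradient(ens.ap.data.mean(axis=0), 1.0)
        t = ueg.times
        # AT of the isolated site
        local_peak_qrs = params.A * params.beta_at / 4.0
        wq = (t >= 140.0) & (t <= 160.0)
        assert np.max(np.abs(remote_dv[wq])) < 0.1 * local_peak_qrs
        assert abs(detect_at(ueg.trace(59), (140.0, 180.0)).time_ms - 150.0) <= 1.0
        # RT of the isolated site
        local_peak_tw = params.A * params.beta_rt / 4.0
        wt = (t >= 440.0) & (t <= 480.0)
        assert np.max(np.abs(remote_dv[wt])) < 0.1 * local_peak_tw
        assert abs(detect_rt(ueg.trace(59), (400.0, 580.0)).time_ms - 460.0) <= 2.0


class TestWindows:
    def test_auto_windows_isolate_qrs_and_twave(self, timing_240, ueg_240):
        at = np.asarray(timing_240.at, float)
        rt = np.asarray(timing_240.rt, float)
        w = auto_windows(ueg_240)
        assert w.qrs[0] <= at.min() and w.qrs[1] >= at.max()
        assert w.twave[0] <= rt.min() and w.twave[1] >= rt.max()

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            BeatWindows(qrs=(0.0, 300.0), twave=(200.0, 500.0))

    def test_markermap_csv_roundtrip(self, tmp_path):
        mm = MarkerMap.from_arrays(np.arange(4), [10.0, 20.0, 30.0, np.nan], [200.0, 210.0, 25.0, 300.0])
        p = tmp_path / "m.csv"
        mm.to_csv(p)
        back = MarkerMap.from_csv(p)
        assert np.array_equal(np.asarray(back.valid), [True, True, False, False])
        assert np.allclose(np.asarray(back.at)[:3], [10.0, 20.0, 30.0])
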