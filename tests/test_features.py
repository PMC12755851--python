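"""Spike detection, waveforms, the 22 AP attributes, and the STA."""

import numpy as np
import pytest

from neuroclass.datatypes import CurrentTrace, Recording
from neuroclass.features import (
    AP_FEATURE_NAMES,
    SpikeTrain,
    ap_feature_vector,
    ap_width_amplitude,
    compute_sta,
    detect_spikes,
    extract_waveforms,
    feature_dict_to_vector,
    spike_threshold,
)


def _spiky_trace(spike_samples, n=20_000, dt=0.05, peak=30.0, base=-70.0):
    V = np.full(n, base)
    for s in spike_samples:
        V[s] = peak
    return V, dt


class TestDetectSpikes:
    def test_two_clear_peaks(self):
        V, dt = _spiky_trace([1000, 2000])
        sp = detect_spikes(V, dt)
        assert np.allclose(sp.times, [50.0, 100.0])

    def test_all_subthreshold_empty(self):
        V = np.full(1000, -70.0) + np.sin(np.arange(1000) / 30.0)
        assert len(detect_spikes(V, 0.05)) == 0

    def test_height_criterion(self):
        V, dt = _spiky_trace([500], peak=15.0)
        assert len(detect_spikes(V, dt)) == 0  # below the 20 mV default
        assert len(detect_spikes(V, dt, height=10.0)) == 1

    def test_min_distance_suppresses_close_peaks(self):
        V, dt = _spiky_trace([1000, 1030])  # 1.5 ms apart
        assert len(detect_spikes(V, dt, min_distance=4.0)) == 1

    def test_plateau_resolves_to_first_sample(self):
        V = np.full(2000, -70.0)
        V[500:505] = 25.0
        sp = detect_spikes(V, 0.05)
        assert sp.times[0] == pytest.approx(500 * 0.05)


class TestWaveforms:
    def test_window_sample_count(self):
        V, dt = _spiky_trace([2000, 6000])
        ws = extract_waveforms(V, dt, detect_spikes(V, dt), 2.0, 3.0)
        assert ws.waveforms.shape == (2, 100)  # 5 ms at 20 kHz

    def test_short_isi_pair_both_excluded(self):
        V, dt = _spiky_trace([2000, 2040, 10_000])  # first two 2 ms apart
        sp = SpikeTrain(times=np.array([100.0, 102.0, 500.0]))
        ws = extract_waveforms(V, dt, sp, 2.0, 3.0, isi_min=3.0)
        assert ws.waveforms.shape[0] == 1
        assert ws.spike_times[0] == pytest.approx(500.0)

    def test_identical_waveforms_mean_is_member(self):
        V, dt = _spiky_trace([2000, 6000, 10_000])
        ws = extract_waveforms(V, dt, detect_spikes(V, dt), 2.0, 3.0)
        assert np.allclose(ws.mean_waveform, ws.waveforms[0])

    def test_edge_spikes_dropped(self):
        V, dt = _spiky_trace([10, 5000])
        ws = extract_waveforms(V, dt, detect_spikes(V, dt), 2.0, 3.0)
        assert ws.waveforms.shape[0] == 1


class TestThresholdWidthAmplitude:
    def _triangle(self, dt=0.05, thresh=-40.0, peak=30.0, rise=0.5, fall=0.5,
                  base=-70.0):
        """Piecewise-linear spike rising from base through thresh to peak."""
        n_pre = int(2.0 / dt)
        n_rise = int(rise / dt)
        n_fall = int(fall / dt)
        # slow approach below 25 mV/ms, then fast rise
        approach = np.linspace(base, thresh, n_pre, endpoint=False)
        up = np.linspace(thresh, peak, n_rise, endpoint=False)
        down = np.linspace(peak, base, n_fall + 1)[1:]
        V = np.concatenate([np.full(400, base), approach, up, [peak], down,
                            np.full(400, base)])
        peak_idx = 400 + n_pre + n_rise
        return V, peak_idx * dt

    def test_threshold_at_slope_criterion_crossing(self):
        # dV/dt first reaches 25 mV/ms exactly where the fast rise begins
        V, t_peak = self._triangle(thresh=-40.0)
        th = spike_threshold(V, 0.05, t_peak, slope_criterion=25.0)
        assert th == pytest.approx(-40.0, abs=0.2)

    def test_never_steep_enough_gives_nan(self):
        V = np.linspace(-70.0, 30.0, 10_000)  # 0.2 mV/ms everywhere
        assert np.isnan(spike_threshold(V, 0.05, 450.0))

    def test_triangular_width_and_amplitude(self):
        V, t_peak = self._triangle(thresh=-40.0, peak=30.0, rise=0.5, fall=0.5 * 100 / 70)
        w, a = ap_width_amplitude(V, 0.05, t_peak, -40.0)
        assert a == pytest.approx(70.0)
        # crossing back below -40 occurs 0.5 ms after the peak by construction
        assert w == pytest.approx(1.0, abs=0.06)

    def test_monotone_rise_missing_width(self):
        V = np.concatenate([np.full(100, -70.0), np.linspace(-70, 30, 100)])
        w, a = ap_width_amplitude(V, 0.05, 199 * 0.05, -40.0)
        assert np.isnan(w)


class TestAPFeatureVector:
    def test_uniform_isi_train(self):
        dt = 0.05
        samples = np.arange(2000, 42_000, 2000)  # 100 ms apart
        V, _ = _spiky_trace(list(samples), n=44_000)
        I = CurrentTrace(values=np.zeros(44_000), dt=dt)
        rec = Recording(V=V, I=I, dt=dt, spike_times=samples * dt)
        f = ap_feature_vector(rec, "FN")
        assert f["isi_mean"] == f["isi_median"] == f["isi_min"] == f["isi_max"] == 100.0
        assert f["instantaneous_rate"] == pytest.approx(10.0)

    def test_fn_firing_rate_counts_whole_trial(self):
        dt = 0.05
        n = int(360_000.0 / dt)  # 360 s
        samples = np.linspace(10_000, n - 10_000, 36).astype(int)
        V = np.full(n, -70.0, dtype=np.float32)
        V[samples] = 30.0
        I = CurrentTrace(values=np.zeros(2), dt=dt)
        # feature extraction only needs V + detected spikes; build directly
        rec = Recording(V=V, I=CurrentTrace(values=np.zeros(n), dt=dt), dt=dt,
                        spike_times=samples * dt)
        f = ap_feature_vector(rec, "FN")
        assert f["ap_count"] == 36
        assert f["firing_rate"] == pytest.approx(0.1)

    def test_sh_first_spiking_step(self):
        # neuron first spikes on the 120 pA step
        dt = 0.05
        recs = []
        for amp in (40.0, 80.0, 120.0, 160.0):
            n = int(700.0 / dt)
            V = np.full(n, -70.0)
            if amp >= 120.0:
                for k, s in enumerate(range(3000, 12_000, 2000)):
                    V[s] = 30.0
            I = CurrentTrace(values=np.zeros(n), dt=dt, protocol_tag="SH",
                             meta={"amplitude": amp, "onset": 100.0,
                                   "step_duration": 500.0})
            recs.append(Recording(V=V, I=I, dt=dt, spike_times=np.empty(0)))
        f = ap_feature_vector(recs, "SH")
        assert f["current_at_first_spike"] == 120.0
        assert f["time_to_first_spike"] == pytest.approx(50.0)  # 150 ms - onset
        assert f["ap_count"] == 5.0  # spikes inside the 160 pA step window

    def test_vector_order_and_length(self):
        assert len(AP_FEATURE_NAMES) == 22
        f = dict.fromkeys(AP_FEATURE_NAMES, 0.0)
        assert feature_dict_to_vector(f).shape == (22,)

    def test_fewer_than_two_spikes_incomplete(self):
        dt = 0.05
        V, _ = _spiky_trace([2000])
        rec = Recording(V=V, I=CurrentTrace(values=np.zeros(V.size), dt=dt),
                        dt=dt, spike_times=np.array([100.0]))
        f = ap_feature_vector(rec, "FN")
        assert f["incomplete"]
        assert np.isnan(f["isi_mean"])


class TestSTA:
    def test_single_spike_equals_preceding_segment(self):
        rng = np.random.default_rng(0)
        cur = CurrentTrace(values=rng.normal(0, 50, 4000), dt=0.05)
        sp = SpikeTrain(times=np.array([150.0]))
        sta = compute_sta(cur, sp, window=100.0)
        seg = cur.values[3000 - 2000: 3000]
        assert np.allclose(sta.raw, seg)
        assert sta.values.size == 2000  # 100 ms at 20 kHz

    def test_l2_norm_is_one(self):
        rng = np.random.default_rng(1)
        cur = CurrentTrace(values=rng.normal(0, 50, 100_000), dt=0.05)
        times = np.sort(rng.choice(np.arange(2001, 99_999), 300, replace=False)) * 0.05
        sta = compute_sta(cur, SpikeTrain(times=times), window=100.0)
        assert np.linalg.norm(sta.values) == pytest.approx(1.0, abs=1e-12)

    def test_independent_spikes_sta_shrinks_like_sqrt_n(self):
        # law of large numbers: raw STA RMS ~ sigma/sqrt(N)
        rng = np.random.default_rng(2)
        dt = 0.05
        cur = CurrentTrace(values=rng.normal(0, 1, 4_000_000), dt=dt)
        rms = {}
        for n_spk in (100, 10_000):
            idx = np.sort(rng.choice(np.arange(2000, 3_999_999), n_spk,
                                     replace=False))
            sta = compute_sta(cur, SpikeTrain(times=idx * dt), window=100.0)
            rms[n_spk] = np.sqrt(np.mean(sta.raw**2))
        ratio = rms[100] / rms[10_000]
        assert 5.0 < ratio < 20.0  # expected 10

    def test_spikes_without_window_dropped_or_error(self):
        cur = CurrentTrace(values=np.ones(3000), dt=0.05)
        with pytest.raises(ValueError):
            compute_sta(cur, SpikeTrain(times=np.array([50.0])), window=100.0)

    def test_feature_vector_padding_invariance(self):
        # appending spike-free padding changes FN rate only through T
        dt = 0.05
        samples = list(range(2000, 40_000, 2000))
        V, _ = _spiky_trace(samples, n=42_000)
        rec = Recording(V=V, I=CurrentTrace(values=np.zeros(42_000), dt=dt),
                        dt=dt, spike_times=np.array(samples) * dt)
        Vp = np.concatenate([V, np.full(42_000, -70.0)])
        rec_p = Recording(V=Vp, I=CurrentTrace(values=np.zeros(84_000), dt=dt),
                          dt=dt, spike_times=np.array(samples) * dt)
        f = ap_feature_vector(rec, "FN")
        fp = ap_feature_vector(rec_p, "FN")
        assert fp["firing_rate"] == pytest.approx(f["firing_rate"] / 2.0)
        for k in ("isi_mean", "width_mean", "threshold_mean", "amplitude_mean"):
            if np.isfinite(f[k]) or np.isfinite(fp[k]):
                assert fp[k] == pytest.approx(f[k], nan_ok=True)
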