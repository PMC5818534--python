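"""Spike detection and feature extraction against constructed fixtures."""

import numpy as np
import pytest

from neurofit.ephys_features import (FEATURE_NAMES, adaptation_index,
                                     aggregate_targets, ap_width,
                                     detect_spikes, train_features)
from neurofit.io_formats import Sweep
from neurofit.protocols import StimulusProtocol

FS = 20000.0


def _sweep(v, stimulus=None):
    n = v.size
    return Sweep(t=np.arange(n) / FS, i_inj=np.zeros(n), v=v,
                 sampling_rate=FS, stimulus=stimulus)


def _spike_waveform():
    """A stereotyped AP: rise to +30 in 0.5 ms, fall to -65 trough, recover."""
    up = np.linspace(-55.0, 30.0, 10)           # 0.5 ms upstroke
    down = np.linspace(30.0, -65.0, 16)[1:]     # 0.75 ms downstroke
    recover = np.linspace(-65.0, -60.0, 40)[1:]
    return np.concatenate([up, down, recover])


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        sw = _sweep(np.full(4000, -70.0))
        assert len(detect_spikes(sw)) == 0

    def test_pasted_waveforms_found_at_known_times(self):
        wave = _spike_waveform()
        v = np.full(20000, -70.0)
        locs = [2000, 5000, 8000, 12000, 17000]
        for i in locs:
            v[i:i + wave.size] = wave
        sw = _sweep(v)
        spikes = detect_spikes(sw)
        assert len(spikes) == 5
        for found, planted in zip(spikes.threshold_idx, locs):
            assert abs(found - planted) <= 3  # within a few samples of onset

    def test_lower_threshold_never_fewer_spikes(self):
        wave = _spike_waveform()
        v = np.full(8000, -70.0)
        v[2000:2000 + wave.size] = wave
        v[5000:5000 + wave.size] = wave * 0.5 - 35.0  # smaller deflection
        sw = _sweep(v)
        counts = [len(detect_spikes(sw, dvdt_threshold=thr))
                  for thr in (80.0, 40.0, 20.0, 10.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_landmarks_ordered(self):
        wave = _spike_waveform()
        v = np.full(8000, -70.0)
        v[2000:2000 + wave.size] = wave
        sw = _sweep(v)
        s = detect_spikes(sw)
        assert s.threshold_idx[0] < s.peak_idx[0] <= s.fast_trough_idx[0] \
            <= s.slow_trough_idx[0]


class TestApWidth:
    def _triangle(self, base_ms=2.0, trough=-60.0, peak=40.0):
        """Symmetric triangular spike of given base width."""
        half = int(base_ms / 2 * FS / 1000)
        up = np.linspace(trough, peak, half + 1)
        down = np.linspace(peak, trough, half + 1)[1:]
        v = np.concatenate([np.full(200, trough), up, down, np.full(400, trough)])
        return v, 200 + half  # peak index

    def test_triangular_spike_half_width(self):
        v, pk = self._triangle()
        sw = _sweep(v)
        ft = pk + int(1.0 * FS / 1000)  # trough reached 1 ms after peak
        # half height -10 mV; width of a 2 ms-base triangle there = 1 ms
        assert ap_width(sw, pk, ft) == pytest.approx(1.0, abs=0.01)

    def test_time_scaling_doubles_width(self):
        v, pk = self._triangle(base_ms=4.0)
        sw = _sweep(v)
        ft = pk + int(2.0 * FS / 1000)
        assert ap_width(sw, pk, ft) == pytest.approx(2.0, abs=0.02)

    def test_rectangular_pulse_width_is_pulse_width(self):
        v = np.full(2000, -60.0)
        v[500:520] = 40.0   # 1 ms rectangle
        sw = _sweep(v)
        w = ap_width(sw, 510, 540)
        assert w == pytest.approx(1.0, abs=0.1)


class TestAdaptationIndex:
    def test_hand_computed_example(self):
        # (10->20: 10/30) and (20->40: 20/60), mean = 1/3
        assert adaptation_index([0.010, 0.020, 0.040]) == pytest.approx(1 / 3)

    def test_constant_isis_zero(self):
        assert adaptation_index([0.05, 0.05, 0.05, 0.05]) == 0.0

    def test_reversal_negates(self):
        isis = [0.01, 0.03, 0.02, 0.05]
        assert adaptation_index(isis[::-1]) == pytest.approx(
            -adaptation_index(isis))

    def test_too_few_isis_rejected(self):
        with pytest.raises(ValueError):
            adaptation_index([0.01])


class TestTrainFeatures:
    def _regular_train(self, n_spikes=10, start=0.2, isi_s=0.08):
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=100.0, total_duration=1.35)
        wave = _spike_waveform()
        v = np.full(int(1.35 * FS), -70.0)
        for k in range(n_spikes):
            i = int((start + k * isi_s) * FS)
            v[i:i + wave.size] = wave
        return _sweep(v, proto)

    def test_rate_is_count_over_duration(self):
        sw = self._regular_train(10)
        f = train_features(detect_spikes(sw), sw)
        assert f["avg_rate"] == pytest.approx(10.0)

    def test_equally_spaced_spikes_zero_cv_and_adaptation(self):
        sw = self._regular_train(10)
        f = train_features(detect_spikes(sw), sw)
        # one-sample detection jitter bounds both statistics
        assert f["isi_cv"] == pytest.approx(0.0, abs=1e-3)
        assert f["adaptation_index"] == pytest.approx(0.0, abs=1e-3)
        assert f["mean_isi"] == pytest.approx(0.08, abs=1e-3)
        assert f["first_isi"] == pytest.approx(0.08, abs=1e-3)

    def test_latency_and_baseline(self):
        sw = self._regular_train(5, start=0.25)
        f = train_features(detect_spikes(sw), sw)
        assert f["latency"] == pytest.approx(0.15, abs=2e-3)
        assert f["baseline_v"] == pytest.approx(-70.0, abs=0.01)

    def test_zero_spikes_flags_shape_features(self):
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=10.0, total_duration=1.35)
        sw = _sweep(np.full(int(1.35 * FS), -70.0), proto)
        f = train_features(detect_spikes(sw), sw)
        assert f["avg_rate"] == 0.0
        assert f["ap_peak"] is None and f["latency"] is None

    def test_rate_times_duration_is_integer_count(self):
        for n in (3, 7, 12):
            sw = self._regular_train(n, isi_s=0.05)
            f = train_features(detect_spikes(sw), sw)
            assert f["avg_rate"] * sw.stimulus.duration == pytest.approx(n)

    def test_final_spike_slow_trough_bounded_by_stimulus_end(self):
        """A final spike near stimulus end must not search beyond it."""
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=100.0, total_duration=1.35)
        wave = _spike_waveform()
        v = np.full(int(1.35 * FS), -70.0)
        i_last = int(1.05 * FS)
        v[i_last:i_last + wave.size] = wave
        v[int(1.2 * FS):] = -90.0  # deep dip after stimulus end
        sw = _sweep(v, proto)
        s = detect_spikes(sw, stim_end=proto.end)
        assert s.slow_trough_idx[0] <= int(proto.end * FS)


class TestAggregateTargets:
    def _fv(self, rate):
        fv = dict.fromkeys(FEATURE_NAMES)
        fv["avg_rate"] = rate
        fv["baseline_v"] = -70.0
        return fv

    def test_single_repeat_sd_absent(self):
        t = aggregate_targets([self._fv(10.0)], {n: 1.0 for n in FEATURE_NAMES})
        assert t.sd == {}
        assert t.sigma("avg_rate") == 1.0

    def test_identical_repeats_zero_sd(self):
        t = aggregate_targets([self._fv(10.0)] * 3,
                              {n: 1.0 for n in FEATURE_NAMES})
        assert t.sd["avg_rate"] == 0.0
        # floor governs when SD collapses
        assert t.sigma("avg_rate") == 1.0

    def test_sample_sd_convention(self):
        t = aggregate_targets([self._fv(9.0), self._fv(11.0)],
                              {n: 0.1 for n in FEATURE_NAMES})
        assert t.mean["avg_rate"] == pytest.approx(10.0)
        assert t.sd["avg_rate"] == pytest.approx(np.sqrt(2.0), rel=1e-9)
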