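import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgtracks import preprocess, synth
from ecgtracks.io import EcgRecord


def _amplitude(x):
    core = x[len(x) // 4 : -len(x) // 4]  # avoid filter edge transients
    return np.abs(core).max()


class TestBandpass:
    def test_baseline_wander_attenuated(self):
        fs, t = 300.0, np.arange(0, 20, 1 / 300.0)
        x = np.sin(2 * np.pi * 0.25 * t)
        y = preprocess.bandpass(x, fs)
        assert 20 * np.log10(_amplitude(y) / 1.0) <= -20.0

    def test_passband_preserved(self):
        fs, t = 300.0, np.arange(0, 20, 1 / 300.0)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = preprocess.bandpass(x, fs)
        assert abs(20 * np.log10(_amplitude(y))) < 1.0

    def test_zero_in_zero_out_same_length(self):
        y = preprocess.bandpass(np.zeros(1000), 300.0)
        assert y.shape == (1000,) and np.allclose(y, 0.0)

    def test_fs_too_low(self):
        with pytest.raises(ValueError, match="fs"):
            preprocess.bandpass(np.zeros(1000), 80.0)


class TestDetectRpeaks:
    def test_flat_signal_no_peaks(self):
        beats = preprocess.detect_rpeaks(np.zeros(3000), 300.0)
        assert beats.r_peaks.size == 0

    def test_short_input_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            beats = preprocess.detect_rpeaks(np.zeros(100), 300.0)
        assert beats.r_peaks.size == 0

    def test_sinus_sensitivity_ppv(self, sinus_record):
        rec, gt = sinus_record
        beats = preprocess.detect_rpeaks(rec.signal[0], rec.fs)
        det_t = beats.r_peaks / rec.fs
        matched = sum(np.abs(det_t - t).min() <= 0.05
                      for t in gt.r_peak_times)
        sens = matched / len(gt.r_peak_times)
        ppv = sum(np.abs(gt.r_peak_times - d).min() <= 0.05
                  for d in det_t) / len(det_t)
        assert sens >= 0.95 and ppv >= 0.95

    def test_brady_mean_rr(self):
        spec = synth.RhythmSpec.for_class("brady", seed=7)
        rec, _ = synth.simulate_record(spec, duration_s=60.0, fs=300.0)
        beats = preprocess.detect_rpeaks(rec.signal[0], rec.fs)
        assert abs(np.mean(beats.rr) - 1.2) / 1.2 < 0.05

    def test_shift_equivariance(self, sinus_record):
        rec, _ = sinus_record
        x = rec.signal[0]
        k = 150
        a = preprocess.detect_rpeaks(x[:-k], rec.fs).r_peaks
        b = preprocess.detect_rpeaks(x[k:-0 or None], rec.fs).r_peaks
        # compare peaks in the interior common to both windows
        a_in = a[(a > k + 300) & (a < len(x) - k - 300)]
        b_in = b + k
        b_in = b_in[(b_in > k + 300) & (b_in < len(x) - k - 300)]
        assert np.array_equal(a_in, b_in)


class TestExtractNN:
    def _beats(self, rr):
        peaks = np.concatenate([[0], np.cumsum(np.asarray(rr) * 300)])
        return preprocess.BeatSeries(r_peaks=peaks.astype(int), fs=300.0)

    def test_all_normal(self):
        out = preprocess.extract_nn(self._beats([0.8, 0.8, 0.8]))
        assert np.allclose(out.nn, [0.8, 0.8, 0.8])

    def test_physiological_bound(self):
        out = preprocess.extract_nn(self._beats([0.8, 0.1, 0.8]))
        assert np.allclose(out.nn, [0.8, 0.8])

    def test_median_deviation_rule(self):
        rr = [0.8, 0.8, 0.8, 0.8, 0.8, 1.3, 0.8]  # 1.3 is 62% above median
        out = preprocess.extract_nn(self._beats(rr))
        assert 1.3 not in out.nn and len(out.nn) == 6

    def test_too_few_peaks(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = preprocess.extract_nn(
                preprocess.BeatSeries(r_peaks=np.array([0, 240]), fs=300.0))
        assert out.nn.size == 0


class TestTransform1D:
    def _rec(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return EcgRecord(record_id="t", signal=x, fs=300.0,
                         lead_names=[f"L{i}" for i in range(x.shape[0])],
                         labels={"sinus"})

    def test_two_point_example(self):
        out = preprocess.transform_1d(self._rec([1.0, 3.0, 6.0]))
        assert np.allclose(out.x, [[-1.0, 1.0]])

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        a = preprocess.transform_1d(self._rec(x)).x
        b = preprocess.transform_1d(self._rec(3.7 * x + 2.0)).x
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_gives_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess.transform_1d(self._rec(np.full(100, 2.0)))
        assert np.allclose(out.x, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=200),
           st.integers(0, 1000))
    def test_invariants_property(self, values, salt):
        x = np.asarray(values) + np.sin(np.arange(len(values)) + salt)
        if np.ptp(np.diff(x)) == 0:
            return
        out = preprocess.transform_1d(self._rec(x)).x
        assert out.shape == (1, len(x) - 1)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6


class TestPrepareWindow:
    def test_resample_and_crop(self):
        spec = synth.RhythmSpec.for_class("sinus", seed=1)
        rec, _ = synth.simulate_record(spec, duration_s=20.0, fs=500.0)
        out = preprocess.prepare_window(rec, target_fs=300.0, window_s=10.0)
        assert out.fs == 300.0 and out.n_samples == 3000

    def test_zero_pad_short_record(self):
        spec = synth.RhythmSpec.for_class("sinus", seed=1)
        rec, _ = synth.simulate_record(spec, duration_s=5.0, fs=300.0)
        out = preprocess.prepare_window(rec, target_fs=300.0, window_s=10.0)
        assert out.n_samples == 3000
        assert np.allclose(out.signal[:, 1600:], 0.0)
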