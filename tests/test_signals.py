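"""Preprocessing: filtering, resampling, STA, derivative, phase, binning."""

import numpy as np
import pytest
from scipy.signal import periodogram

import lfp2spike as l
from lfp2spike.signals import (
    DegenerateFeatureError,
    InvalidBandError,
    Trace,
    slice_trials,
)


def _sine(freq, fs, dur=2.0, phase=0.0):
    t = np.arange(0.0, dur, 1.0 / fs)
    return Trace(np.sin(2 * np.pi * freq * t + phase), fs)


class TestBandpass:
    def test_in_band_passthrough(self):
        tr = _sine(5.0, 500.0, dur=10.0)
        out = l.bandpass_filter(tr, 1.0, 100.0)
        core = slice(500, -500)  # trim filter edges
        ratio = np.abs(out.samples[core]).max() / np.abs(tr.samples[core]).max()
        assert 0.95 < ratio < 1.05

    def test_out_of_band_rejection(self):
        tr = _sine(200.0, 500.0, dur=10.0)
        out = l.bandpass_filter(tr, 1.0, 100.0)
        assert np.abs(out.samples[500:-500]).max() < 0.1

    def test_stopband_power_fraction(self, rng):
        tr = Trace(rng.standard_normal(50000), 500.0)
        out = l.bandpass_filter(tr, 1.0, 100.0)
        f, p = periodogram(out.samples, fs=500.0)
        stop = p[f > 150.0].sum()
        inband = p[(f >= 1.0) & (f <= 100.0)].sum()
        assert stop < 0.01 * inband

    @pytest.mark.parametrize("band", [(0.0, 100.0), (100.0, 1.0), (1.0, 300.0)])
    def test_invalid_band(self, band):
        tr = _sine(5.0, 500.0)
        with pytest.raises(InvalidBandError):
            l.bandpass_filter(tr, *band)


class TestDownsample:
    def test_length_ratio_64(self):
        tr = _sine(10.0, 32000.0, dur=1.0)
        out = l.downsample(tr, 500.0)
        assert out.fs == 500.0
        assert abs(out.samples.size - tr.samples.size / 64) <= 1

    def test_identity(self):
        tr = _sine(10.0, 500.0)
        assert l.downsample(tr, 500.0) is tr

    def test_sine_preserved(self):
        tr = _sine(10.0, 32000.0, dur=2.0)
        out = l.downsample(tr, 500.0)
        ref = np.sin(2 * np.pi * 10.0 * np.arange(out.samples.size) / 500.0)
        core = slice(50, -50)
        r = np.corrcoef(out.samples[core], ref[core])[0, 1]
        assert r > 0.999

    def test_upsample_rejected(self):
        with pytest.raises(ValueError):
            l.downsample(_sine(10.0, 500.0), 1000.0)


class TestSTA:
    def test_recovers_repeated_bump(self):
        fs = 500.0
        x = np.zeros(5000)
        bump = np.array([0.2, 1.0, 0.2])
        spike_idx = np.arange(100, 4900, 100)
        for i in spike_idx:
            x[i - 1 : i + 2] += bump
        spikes = l.SpikeTrain(spike_idx / fs)
        kern = l.spike_triggered_average(Trace(x, fs), spikes, half_window=10.0)
        mid = kern.size // 2
        assert kern[mid] == pytest.approx(1.0)
        assert kern[mid - 1] == pytest.approx(0.2)

    def test_null_sta_small(self, rng):
        fs = 1000.0
        x = rng.standard_normal(200000)
        t = np.sort(rng.choice(np.arange(1000, 199000), 1000, replace=False)) / fs
        kern = l.spike_triggered_average(Trace(x, fs), l.SpikeTrain(t), 20.0)
        bound = 3.0 / np.sqrt(1000)
        assert np.mean(np.abs(kern) < bound) >= 0.95

    def test_single_spike_is_segment(self):
        fs = 500.0
        x = np.arange(100.0)
        kern = l.spike_triggered_average(
            Trace(x, fs), l.SpikeTrain([50 / fs]), half_window=4.0
        )
        np.testing.assert_allclose(kern, x[48:53])

    def test_no_usable_spike(self):
        with pytest.raises(ValueError):
            l.spike_triggered_average(
                Trace(np.zeros(10), 500.0), l.SpikeTrain([0.0]), 20.0
            )


class TestConvolveSTA:
    def test_impulse_identity(self, rng):
        tr = Trace(rng.standard_normal(100), 500.0)
        out = l.convolve_sta(tr, np.array([1.0]))
        np.testing.assert_allclose(out.samples, tr.samples, atol=1e-12)

    def test_boxcar_smooths_step(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        out = l.convolve_sta(Trace(x, 500.0), np.array([0.5, 0.5]))
        # direct convolution by hand: the step edge is averaged once
        assert out.samples[9] == pytest.approx(0.5) or out.samples[10] == pytest.approx(0.5)

    def test_symmetric_kernel_no_shift(self):
        x = np.zeros(101)
        x[50] = 1.0
        kern = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
        out = l.convolve_sta(Trace(x, 500.0), kern)
        assert int(np.argmax(out.samples)) == 50

    def test_empty_kernel(self):
        with pytest.raises(ValueError):
            l.convolve_sta(Trace(np.zeros(10), 500.0), np.array([]))


class TestDerivative:
    def test_sine_derivative(self):
        fs, f = 5000.0, 5.0
        tr = _sine(f, fs, dur=2.0)
        d = l.derivative(tr)
        t = np.arange(0.0, 2.0, 1.0 / fs)
        expect = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        core = slice(10, -10)
        err = np.abs(d.samples[core] - expect[core]).max() / (2 * np.pi * f)
        assert err < 0.01

    def test_constant_and_ramp(self):
        fs = 500.0
        np.testing.assert_allclose(
            l.derivative(Trace(np.full(50, 3.0), fs)).samples, 0.0
        )
        ramp = l.derivative(Trace(np.arange(50) * 2.0 / fs, fs))
        np.testing.assert_allclose(ramp.samples, 2.0, rtol=1e-9)

    def test_derivative_inverts_integral(self, rng):
        fs = 500.0
        x = rng.standard_normal(1000)
        integral = np.cumsum(x) / fs
        back = l.derivative(Trace(integral, fs))
        # central differencing a cumulative sum averages adjacent samples
        mid = (x[1:-1] + x[2:]) / 2
        np.testing.assert_allclose(back.samples[1:-1], mid, atol=1e-9)


class TestHilbertPhase:
    def test_cosine_peak_phase(self):
        fs, f = 500.0, 10.0
        t = np.arange(0.0, 2.0, 1.0 / fs)
        tr = Trace(np.cos(2 * np.pi * f * t), fs)
        ph = l.hilbert_phase(tr).samples
        peak = int(round(fs / f))  # an interior signal peak
        trough = int(round(1.5 * fs / f))
        assert abs(ph[peak]) < 0.05
        assert abs(abs(ph[trough]) - np.pi) < 0.05

    def test_quadrature_shift(self):
        fs, f = 500.0, 10.0
        t = np.arange(0.0, 2.0, 1.0 / fs)
        pc = l.hilbert_phase(Trace(np.cos(2 * np.pi * f * t), fs)).samples
        ps = l.hilbert_phase(Trace(np.sin(2 * np.pi * f * t), fs)).samples
        diff = np.angle(np.exp(1j * (pc - ps)))[100:-100]
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.05)

    def test_range_and_zero_trace(self, rng):
        ph = l.hilbert_phase(Trace(rng.standard_normal(1000), 500.0)).samples
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)
        with pytest.raises(ValueError):
            l.hilbert_phase(Trace(np.zeros(100), 500.0))


class TestZscore:
    def test_three_points(self):
        out = l.zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_idempotent(self, rng):
        a = rng.standard_normal((20, 30)) * 4 + 2
        z = l.zscore(a)
        np.testing.assert_allclose(l.zscore(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            l.zscore(np.full(10, 2.0))


class TestBinarize:
    def _events(self, times):
        return l.EventList(np.asarray(times), np.zeros(len(times), dtype=int))

    def test_edge_spike_in_first_bin(self):
        ev = self._events([1.0])
        b = l.binarize_spikes(l.SpikeTrain([1.0]), ev, (0.0, 50.0))
        assert b.matrix[0, 0] == 1 and b.matrix.sum() == 1

    def test_two_spikes_one_bin_clip(self):
        ev = self._events([0.0])
        b = l.binarize_spikes(l.SpikeTrain([0.0005, 0.0015]), ev, (0.0, 50.0))
        assert b.matrix[0, 0] == 1 and b.matrix.sum() == 1

    def test_no_spikes_all_zero(self):
        ev = self._events([0.0, 1.0])
        b = l.binarize_spikes(l.SpikeTrain([]), ev, (0.0, 50.0))
        assert b.matrix.sum() == 0 and b.matrix.shape == (2, 25)

    def test_overlap_rejected(self):
        ev = self._events([0.0, 0.03])
        with pytest.raises(ValueError):
            l.binarize_spikes(l.SpikeTrain([0.01]), ev, (0.0, 50.0))

    def test_spike_conservation(self, rng):
        ev = self._events(np.arange(10) * 1.0)
        times = np.sort(rng.uniform(0.0, 9.06, 300))
        times = np.unique(times)
        b = l.binarize_spikes(l.SpikeTrain(times), ev, (0.0, 50.0))
        in_window = sum(
            int(np.count_nonzero((times >= t) & (times < t + 0.05)))
            for t in ev.times
        )
        assert b.matrix.sum() <= in_window


class TestPSTH:
    def test_mean_and_conservation(self):
        mat = np.array([[1, 0], [0, 0]])
        b = l.BinaryResponse(mat)
        np.testing.assert_allclose(l.psth(b), [0.5, 0.0])
        assert l.psth(b).sum() * b.n_trials == mat.sum()

    def test_all_ones(self):
        b = l.BinaryResponse(np.ones((3, 4)))
        np.testing.assert_allclose(l.psth(b), 1.0)


class TestFeatureAlignment:
    def test_features_and_truth_align(self, aligned_data):
        feats, truth = aligned_data
        assert feats.x1.shape == feats.x2.shape == feats.x3.shape
        assert feats.x1.shape == truth.matrix.shape
        for x in (feats.x1, feats.x2, feats.x3):
            assert abs(x.mean()) < 1e-6
            assert abs(x.std() - 1.0) < 1e-6

    def test_slice_trials_outside_trace(self):
        tr = Trace(np.zeros(100), 500.0)
        ev = l.EventList([0.19], [0])
        with pytest.raises(ValueError):
            slice_trials(tr, ev, (0.0, 50.0))
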