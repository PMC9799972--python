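"""Filtering, analytic signals, multitaper estimates, contrasts."""

import numpy as np
import pytest
from scipy import signal as sps

from rhythmdecode import rhythms as R
from rhythmdecode.session import LFPSignal

FS = 1000.0


def _tone(freq, dur=10.0, amp=1.0, fs=FS):
    t = np.arange(0, dur, 1 / fs)
    return LFPSignal("CA1", 1, fs, amp * np.cos(2 * np.pi * freq * t))


class TestBandpass:
    def test_in_band_tone_is_eigenfunction(self):
        bs = R.bandpass_zero_phase(_tone(25.0), (20, 30))
        core = slice(1000, -1000)
        assert np.allclose(bs.envelope[core], 1.0, atol=0.02)
        # phase 0 at signal peaks
        peaks, _ = sps.find_peaks(bs.filtered[core])
        assert np.abs(bs.phase[core][peaks]).max() < 0.05

    def test_stopband_tone_suppressed(self):
        bs = R.bandpass_zero_phase(_tone(50.0), (20, 30))
        assert bs.envelope[1000:-1000].max() < 0.05

    def test_impulse_response_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        bs = R.bandpass_zero_phase(LFPSignal("CA1", 1, FS, x), (20, 30))
        np.testing.assert_allclose(bs.filtered, bs.filtered[::-1],
                                   rtol=0, atol=1e-8)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            R.bandpass_zero_phase(_tone(25, fs=100.0), (20, 60))

    def test_phase_advances_one_cycle_per_period(self):
        bs = R.bandpass_zero_phase(_tone(25.0), (20, 30))
        unwrapped = np.unwrap(bs.phase[2000:-2000])
        slope = np.polyfit(np.arange(unwrapped.size) / FS, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 25, rel=1e-3)


class TestMultitaper:
    def test_white_noise_spectrum_flat(self, rng):
        sig = LFPSignal("CA1", 1, FS, rng.standard_normal(60000))
        tf = R.multitaper_spectrogram(sig, [10.0, 25.0, 40.0],
                                      pre_s=5, post_s=5)
        mean_spec = tf.values.mean(axis=1)
        band = (tf.freqs > 5) & (tf.freqs < 450)
        assert mean_spec[band].max() / mean_spec[band].min() < 1.5

    def test_zscored_stationary_rows_near_zero(self, rng):
        sig = LFPSignal("CA1", 1, FS, rng.standard_normal(60000))
        tf = R.multitaper_spectrogram(sig, [20.0, 40.0], zscore=True,
                                      pre_s=5, post_s=5)
        assert np.abs(tf.values.mean(axis=1)).max() < 1.0

    def test_odor_locked_tone_bursts_raise_band_power(self, small_session):
        rec, _ = small_session
        ca1 = rec.lfp_by_region("CA1")[0]
        inc = rec.trials[rec.trials["included"]]
        tf = R.multitaper_spectrogram(ca1, inc["port_in"].to_numpy(),
                                      zscore=True, pre_s=1.0, post_s=1.0)
        beta = (tf.freqs >= 20) & (tf.freqs <= 30)
        pre = tf.values[beta][:, tf.times < -0.3].mean()
        post = tf.values[beta][:, (tf.times > 0.1) & (tf.times < 0.7)].mean()
        assert post > pre

    def test_coherence_of_signal_with_itself_is_one(self, rng):
        x = rng.standard_normal(30000)
        a = LFPSignal("CA1", 1, FS, x)
        b = LFPSignal("PFC", 2, FS, x.copy())
        tf = R.multitaper_coherogram(a, b, [10.0, 20.0], pre_s=5, post_s=5)
        assert tf.values.min() > 0.999

    def test_independent_noise_coherence_near_taper_floor(self, rng):
        a = LFPSignal("CA1", 1, FS, rng.standard_normal(30000))
        b = LFPSignal("PFC", 2, FS, rng.standard_normal(30000))
        tf = R.multitaper_coherogram(a, b, [10.0, 20.0], pre_s=5, post_s=5,
                                     n_tapers=5)
        assert tf.values.mean() == pytest.approx(1 / 5, abs=0.08)

    def test_shared_tone_dominates_band_coherence(self, rng):
        t = np.arange(0, 30, 1 / FS)
        tone = np.cos(2 * np.pi * 25 * t)
        a = LFPSignal("CA1", 1, FS, tone + rng.standard_normal(t.size))
        b = LFPSignal("PFC", 2, FS, tone + rng.standard_normal(t.size))
        tf = R.multitaper_coherogram(a, b, [10.0, 20.0], pre_s=5, post_s=5)
        beta = (tf.freqs >= 20) & (tf.freqs <= 30)
        out = (tf.freqs >= 60) & (tf.freqs <= 120)
        assert tf.values[beta].mean() > 3 * tf.values[out].mean()

    def test_coherence_invariant_to_amplitude_scaling(self, rng):
        x = rng.standard_normal(30000)
        y = x + rng.standard_normal(30000)
        a = LFPSignal("CA1", 1, FS, x)
        b = LFPSignal("PFC", 2, FS, y)
        b10 = LFPSignal("PFC", 2, FS, 10.0 * y)
        c1 = R.multitaper_coherogram(a, b, [15.0], pre_s=5, post_s=5)
        c2 = R.multitaper_coherogram(a, b10, [15.0], pre_s=5, post_s=5)
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-9)


class TestConditionContrast:
    def test_identical_conditions_give_p_one(self):
        a = np.arange(10.0)
        res = R.condition_contrast(a, a.copy())
        assert res.p == 1.0 and np.all(res.deltas == 0)

    def test_uniform_positive_shift_is_significant(self):
        a = np.arange(10.0)
        res = R.condition_contrast(a, a + 1.0)
        assert res.p < 0.01

    def test_sessions_missing_a_condition_are_dropped(self):
        a = [1.0, 2.0, np.nan, 4.0]
        b = [2.0, 3.0, 5.0, 6.0]
        with pytest.warns(UserWarning):
            res = R.condition_contrast(a, b)
        assert len(res.values_a) == 3


class TestBootstrapDownsample:
    def test_air_below_all_odor_values_floors_p(self, rng):
        p, _, label = R.bootstrap_downsample_test(
            np.arange(10, 20.0), np.zeros(5), rng=rng)
        assert p < 0.001 and label.startswith("<")

    def test_same_values_give_centered_p(self, rng):
        vals = np.arange(10.0)
        p, _, _ = R.bootstrap_downsample_test(vals, vals.copy(), rng=rng)
        assert 0.3 < p < 0.8

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        for _ in range(200):
            odor = rng.standard_normal(30)
            air = rng.standard_normal(10)
            p, _, _ = R.bootstrap_downsample_test(odor, air, n_boot=200,
                                                  rng=rng)
            rejections += p < 0.05
        assert 0.01 <= rejections / 200 <= 0.12


class TestPhaseOffset:
    def test_pure_delay_maps_to_phase_lag(self):
        t = np.arange(0, 10, 1 / FS)
        a = LFPSignal("CA1", 1, FS, np.cos(2 * np.pi * 25 * t))
        b = LFPSignal("PFC", 2, FS, np.cos(2 * np.pi * 25 * (t - 0.01)))
        ba = R.bandpass_zero_phase(a, (20, 30))
        bb = R.bandpass_zero_phase(b, (20, 30))
        off, res = R.cross_region_phase_offset(ba, bb, [(2.0, 8.0)])
        # 10 ms at 25 Hz = pi/2, A leads
        assert off == pytest.approx(np.pi / 2, abs=0.05)
        assert res > 0.99

    def test_identical_signals_zero_offset(self):
        a = _tone(25.0)
        ba = R.bandpass_zero_phase(a, (20, 30))
        off, res = R.cross_region_phase_offset(ba, ba, [(2.0, 8.0)])
        assert off == pytest.approx(0.0, abs=1e-9) and res == pytest.approx(1.0)

    def test_independent_narrowband_resultant_small(self, rng):
        a = LFPSignal("CA1", 1, FS, rng.standard_normal(20000))
        b = LFPSignal("PFC", 2, FS, rng.standard_normal(20000))
        ba = R.bandpass_zero_phase(a, (20, 30))
        bb = R.bandpass_zero_phase(b, (20, 30))
        _, res = R.cross_region_phase_offset(ba, bb, [(1.0, 19.0)])
        assert res < 0.15

    def test_empty_windows_rejected(self):
        ba = R.bandpass_zero_phase(_tone(25.0), (20, 30))
        with pytest.raises(ValueError):
            R.cross_region_phase_offset(ba, ba, [])
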