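"""Beat detection, IBI construction, ectopic rejection, detrending and
uniform resampling."""

import numpy as np
import pytest
from scipy.signal import periodogram

from hrvcam.beats_hrv import (IBISeries, beats_to_ibi, detrend_poly,
                              ectopic_filter, match_beats, pan_tompkins,
                              resample_tachogram)
from hrvcam.preprocess import preprocess_ecg
from hrvcam.synth_ecg import (BeatTimes, ECGRecord, NoiseConfig, ipfm_beats,
                              render_ecg)
from tests.conftest import constant_modulation


def _beats(times):
    times = np.asarray(times, dtype=float)
    return BeatTimes(times=times, labels=np.array(["normal"] * times.size,
                                                  dtype=object))


class TestPanTompkins:
    def test_clean_60bpm_record_fully_detected(self, clean_record_60bpm):
        det = pan_tompkins(preprocess_ecg(clean_record_60bpm))
        m = match_beats(det, clean_record_60bpm.annotations, tol_ms=50)
        assert len(det) == len(clean_record_60bpm.annotations)
        assert m.sensitivity == 1.0 and m.ppv == 1.0
        assert np.max(np.abs(m.offsets_ms)) <= 10.0

    def test_flat_signal_yields_no_detections(self):
        rec = ECGRecord(fs=250.0, samples=np.zeros(250 * 10))
        assert len(pan_tompkins(rec)) == 0

    def test_refractory_suppresses_close_double_beat(self):
        times = [1.0, 1.15, 2.2, 3.2, 4.2, 5.2, 6.2]
        rec = render_ecg(_beats(times), fs=250.0, noise=NoiseConfig.none(),
                         duration=7.0)
        det = pan_tompkins(rec)
        assert det.times.size > 0
        assert np.min(np.diff(det.times)) >= 0.2

    def test_short_record_rejected(self):
        rec = ECGRecord(fs=250.0, samples=np.zeros(250 * 3))
        with pytest.raises(ValueError):
            pan_tompkins(rec)


class TestMatchBeats:
    def test_identical_lists_are_perfect(self):
        b = _beats([1, 2, 3, 4])
        m = match_beats(b, b)
        assert m.sensitivity == 1.0 and m.ppv == 1.0

    def test_one_missed_beat(self):
        truth = _beats([1, 2, 3, 4, 5])
        det = _beats([1, 2, 4, 5])
        m = match_beats(det, truth)
        assert m.sensitivity == pytest.approx(4 / 5)
        assert m.ppv == 1.0

    def test_shift_beyond_tolerance_matches_nothing(self):
        truth = _beats([1, 2, 3])
        det = _beats([1.2, 2.2, 3.2])
        m = match_beats(det, truth, tol_ms=50)
        assert m.sensitivity == 0.0


class TestBeatsToIbi:
    def test_uniform_beats(self):
        ibi = beats_to_ibi(_beats([0, 1, 2]))
        assert np.allclose(ibi.ibi, [1000.0, 1000.0])
        assert np.allclose(ibi.beat_time, [1.0, 2.0])

    def test_uneven_beats(self):
        ibi = beats_to_ibi(_beats([0, 0.8, 2.0]))
        assert np.allclose(ibi.ibi, [800.0, 1200.0])

    def test_n_beats_give_n_minus_1_intervals(self):
        beats = ipfm_beats(constant_modulation(120.0), 750.0)
        assert beats_to_ibi(beats).ibi.size == len(beats) - 1

    def test_requires_two_beats(self):
        with pytest.raises(ValueError):
            beats_to_ibi(_beats([1.0]))


class TestEctopicFilter:
    def test_flags_the_short_long_pair(self):
        vals = [1000, 1000, 1000, 1000, 1000, 600, 1400, 1000]
        ibi = IBISeries(beat_time=np.cumsum(np.asarray(vals) / 1000.0),
                        ibi=np.asarray(vals, dtype=float), flags=None)
        out = ectopic_filter(ibi)
        assert list(out.flags != "ok") == [False] * 5 + [True, True, False]

    def test_steady_series_untouched(self):
        ibi = IBISeries(beat_time=np.arange(1, 21, dtype=float),
                        ibi=np.full(20, 1000.0), flags=None)
        out = ectopic_filter(ibi)
        assert np.all(out.flags == "ok")
        assert np.allclose(out.ibi, 1000.0)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(4)
        vals = 1000 + 30 * rng.standard_normal(120)
        vals[[30, 31, 70]] = [650, 1400, 1500]
        ibi = IBISeries(beat_time=np.cumsum(vals) / 1000.0, ibi=vals, flags=None)
        once = ectopic_filter(ibi)
        twice = ectopic_filter(IBISeries(beat_time=once.beat_time,
                                         ibi=once.ibi, flags=None))
        assert np.all(twice.flags == "ok")

    def test_unusable_record_raises(self):
        rng = np.random.default_rng(5)
        vals = np.where(np.arange(40) % 2 == 0, 500.0, 1500.0)
        ibi = IBISeries(beat_time=np.cumsum(vals) / 1000.0, ibi=vals, flags=None)
        with pytest.raises(ValueError):
            ectopic_filter(ibi)


class TestDetrendPoly:
    def test_exact_cubic_removed(self):
        t = np.linspace(0, 300, 1200)
        x = 2.0 + 0.01 * t - 1e-4 * t**2 + 5e-7 * t**3
        resid, _, _ = detrend_poly(t, x, order=3)
        assert np.max(np.abs(resid)) <= 1e-9 * max(1.0, np.max(np.abs(x)))

    def test_constant_series_becomes_zero(self):
        t = np.linspace(0, 10, 50)
        resid, _, _ = detrend_poly(t, np.full(50, 7.0), order=3)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_sinusoid_survives_while_trend_power_drops(self):
        t = np.arange(0, 300, 0.25)
        tone = 20 * np.sin(2 * np.pi * 0.25 * t)
        trend = 0.5 * (t - 150) + 2e-3 * (t - 150) ** 2
        resid, _, _ = detrend_poly(t, tone + trend, order=3)
        f, p_before = periodogram(tone + trend - np.mean(tone + trend), fs=4.0)
        _, p_after = periodogram(resid, fs=4.0)
        slow = f < 0.01
        assert p_after[slow].sum() <= 0.05 * p_before[slow].sum()
        k = np.argmin(np.abs(f - 0.25))
        assert p_after[k - 1:k + 2].sum() >= 0.9 * p_before[k - 1:k + 2].sum()

    def test_residual_orthogonal_to_polynomial_basis(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 100, 500)
        x = rng.standard_normal(500)
        resid, _, _ = detrend_poly(t, x, order=3)
        tc = (t - t.mean()) / t.std()
        for k in range(4):
            inner = abs(np.dot(resid, tc**k)) / (
                np.linalg.norm(resid) * np.linalg.norm(tc**k))
            assert inner < 1e-6

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly(np.full(10, 3.0), np.arange(10.0), order=2)


class TestResampleTachogram:
    def test_constant_series_preserved(self):
        ibi = IBISeries(beat_time=np.arange(1, 31, dtype=float),
                        ibi=np.full(30, 1000.0), flags=None)
        tach = resample_tachogram(ibi)
        assert np.allclose(tach.values, 1000.0, atol=1e-9)
        assert np.allclose(np.diff(tach.times), 0.25)

    def test_300s_record_sample_count(self):
        beats = ipfm_beats(constant_modulation(300.0), 850.0)
        ibi = beats_to_ibi(beats)
        tach = resample_tachogram(ibi)
        # grid covers [first, last] beat time: ~2 RR shy of the record length
        span = ibi.beat_time[-1] - ibi.beat_time[0]
        assert tach.values.size == int(np.floor(span * 4.0)) + 1
        assert 1185 <= tach.values.size <= 1200

    def test_modulation_peak_survives_resampling(self, modulated_tachogram):
        f, p = periodogram(modulated_tachogram.values, fs=4.0)
        assert abs(f[np.argmax(p)] - 0.25) <= f[1] - f[0]

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            IBISeries(beat_time=np.array([1.0, 3.0, 2.0, 4.0, 5.0]),
                      ibi=np.full(5, 1000.0), flags=None)


class TestPipelineRecovery:
    def test_noise_free_chain_recovers_true_ibi_under_10ms(self):
        from hrvcam.synth_ecg import ScenarioConfig, generate_modulation
        cfg = ScenarioConfig(a_hf=0.06, a_lf=0.05, noise_sigma=0.0)
        mod = generate_modulation(cfg, 120.0, "baseline", seed=8)
        truth = ipfm_beats(mod, 850.0)
        rec = render_ecg(truth, fs=250.0, noise=NoiseConfig.none(), seed=0,
                         duration=121.0)
        det = pan_tompkins(preprocess_ecg(rec))
        m = match_beats(det, truth, tol_ms=50)
        assert m.sensitivity > 0.99 and m.ppv > 0.99
        true_ibi = beats_to_ibi(truth)
        det_ibi = beats_to_ibi(det)
        interp = np.interp(true_ibi.beat_time, det_ibi.beat_time, det_ibi.ibi)
        mae = np.mean(np.abs(interp - true_ibi.ibi))
        assert mae < 10.0
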