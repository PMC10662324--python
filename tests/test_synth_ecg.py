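"""Generator-level ground truth: modulation spectra, IPFM beat statistics,
ectopic injection mechanics, waveform rendering and cohort assembly."""

import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from hrvcam.beats_hrv import beats_to_ibi, resample_tachogram
from hrvcam.synth_ecg import (IAT_BANDS, ModulationSignal, NoiseConfig,
                              ScenarioConfig, generate_modulation,
                              inject_ectopics, ipfm_beats, make_cohort,
                              render_ecg)
from tests.conftest import constant_modulation


class TestGenerateModulation:
    def test_zero_amplitudes_give_zero_signal(self):
        cfg = ScenarioConfig(a_lf=0.0, a_hf=0.0, noise_sigma=0.0)
        mod = generate_modulation(cfg, 30.0, "baseline", seed=0)
        assert np.allclose(mod.m, 0.0)

    def test_single_tone_power_concentrates_at_its_frequency(self):
        cfg = ScenarioConfig(a_lf=0.0, a_hf=0.1, f_hf=0.25, noise_sigma=0.0)
        mod = generate_modulation(cfg, 64.0, "baseline", seed=1)
        f, p = periodogram(mod.m, fs=1.0 / mod.dt)
        k = np.argmin(np.abs(f - 0.25))
        assert p[k - 1:k + 2].sum() / p.sum() >= 0.99

    def test_deterministic_under_fixed_seed(self):
        cfg = ScenarioConfig()
        a = generate_modulation(cfg, 30.0, "gameplay", seed=7, severity="mild")
        b = generate_modulation(cfg, 30.0, "gameplay", seed=7, severity="mild")
        assert np.array_equal(a.m, b.m)

    def test_gameplay_scales_amplitudes_by_class_multipliers(self):
        cfg = ScenarioConfig(noise_sigma=0.0)
        base = generate_modulation(cfg, 60.0, "baseline", seed=3, severity="severe")
        game = generate_modulation(cfg, 60.0, "gameplay", seed=3, severity="severe")
        assert game.components["hf"][0] == pytest.approx(
            base.components["hf"][0] * cfg.reactivity_hf["severe"])
        assert game.components["lf"][0] == pytest.approx(
            base.components["lf"][0] * cfg.reactivity_lf["severe"])

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            generate_modulation(ScenarioConfig(), 0.0, "baseline", seed=0)

    def test_rate_positivity_invariant_enforced(self):
        t = np.arange(0, 10, 0.004)
        with pytest.raises(ValueError):
            ModulationSignal(t=t, m=np.full_like(t, -1.5))


class TestIpfmBeats:
    @pytest.mark.parametrize("mean_rr,duration,expected", [
        (1000.0, 60.0, 60), (500.0, 30.0, 60)])
    def test_constant_rate_beat_count(self, mean_rr, duration, expected):
        beats = ipfm_beats(constant_modulation(duration), mean_rr)
        assert len(beats) == expected
        assert np.allclose(np.diff(beats.times), mean_rr / 1000.0, atol=0.004)

    def test_modulation_recovered_in_tachogram_spectrum(self):
        cfg = ScenarioConfig(a_lf=0.0, a_hf=0.1, f_hf=0.25, noise_sigma=0.0)
        mod = generate_modulation(cfg, 300.0, "baseline", seed=2)
        tach = resample_tachogram(beats_to_ibi(ipfm_beats(mod, 900.0)))
        f, p = periodogram(tach.values - tach.values.mean(), fs=4.0)
        df = f[1] - f[0]
        assert abs(f[np.argmax(p)] - 0.25) <= df

    def test_mean_rate_matches_mean_rr(self):
        cfg = ScenarioConfig(noise_sigma=0.01)
        for seed in (0, 1, 2):
            mod = generate_modulation(cfg, 300.0, "baseline", seed=seed)
            ibi = beats_to_ibi(ipfm_beats(mod, 850.0))
            assert abs(ibi.ibi.mean() - 850.0) / 850.0 < 0.02

    def test_rejects_coarse_grid(self):
        t = np.arange(0, 60, 0.05)
        with pytest.raises(ValueError):
            ipfm_beats(ModulationSignal(t=t, m=np.zeros_like(t)), 1000.0)

    def test_times_strictly_increasing(self):
        cfg = ScenarioConfig(noise_sigma=0.02)
        mod = generate_modulation(cfg, 120.0, "baseline", seed=9)
        beats = ipfm_beats(mod, 600.0)
        assert np.all(np.diff(beats.times) > 0)


class TestInjectEctopics:
    def test_zero_rate_is_identity(self):
        beats = ipfm_beats(constant_modulation(60.0), 1000.0)
        out = inject_ectopics(beats, 0.0, seed=0)
        assert np.array_equal(out.times, beats.times)
        assert np.all(out.labels == "normal")

    def test_each_ectopic_shortens_then_lengthens_by_over_20pct(self):
        beats = ipfm_beats(constant_modulation(300.0), 1000.0)
        out = inject_ectopics(beats, 4.0, seed=3)
        ect = np.nonzero(out.labels == "ectopic")[0]
        assert ect.size > 0
        d = np.diff(out.times)
        for i in ect:
            assert d[i - 1] < 0.8        # shortened by >20 % of the 1 s RR
            assert d[i] > 1.2            # compensatory pause

    def test_count_matches_rate_over_seeds(self):
        beats = ipfm_beats(constant_modulation(300.0), 1000.0)
        counts = [int((inject_ectopics(beats, 2.0, seed=s).labels
                       == "ectopic").sum()) for s in range(30)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 10.0) <= 2 * se + 1e-9

    def test_ordering_preserved(self):
        cfg = ScenarioConfig(noise_sigma=0.02)
        for seed in range(5):
            mod = generate_modulation(cfg, 300.0, "baseline", seed=seed)
            out = inject_ectopics(ipfm_beats(mod, 700.0), 5.0, seed=seed)
            assert np.all(np.diff(out.times) > 0)


class TestRenderEcg:
    def test_no_beats_gives_flat_record(self):
        rec = render_ecg(
            __import__("hrvcam").synth_ecg.BeatTimes(
                times=np.empty(0), labels=np.empty(0, dtype=object)),
            fs=250.0, noise=NoiseConfig.none(), duration=5.0)
        assert np.allclose(rec.samples, 0.0)

    def test_one_r_peak_per_beat_at_annotated_time(self, clean_record_60bpm):
        rec = clean_record_60bpm
        peaks, _ = find_peaks(rec.samples, height=0.55)
        assert peaks.size == len(rec.annotations)
        offsets = peaks / rec.fs - rec.annotations.times
        assert np.max(np.abs(offsets)) <= 0.010

    def test_beats_beyond_duration_rejected(self):
        beats = ipfm_beats(constant_modulation(60.0), 1000.0)
        with pytest.raises(ValueError):
            render_ecg(beats, fs=250.0, duration=30.0)

    def test_powerline_noise_is_a_60hz_line(self):
        beats = ipfm_beats(constant_modulation(30.0), 1000.0)
        noise = NoiseConfig(wander_mv=0.0, powerline_mv=0.05, emg_sigma_mv=0.0)
        rec = render_ecg(beats, fs=250.0, noise=noise, seed=1, duration=31.0)
        clean = render_ecg(beats, fs=250.0, noise=NoiseConfig.none(),
                           duration=31.0)
        f, p = periodogram(rec.samples - clean.samples, fs=250.0)
        assert abs(f[np.argmax(p)] - 60.0) < 0.5


class TestMakeCohort:
    def test_single_subject_has_four_records(self):
        cohort = make_cohort(ScenarioConfig(), (1, 0, 0, 0), seed=0,
                             render=False)
        assert len(cohort.subjects) == 1
        assert cohort.n_records == 4
        phases = [r.phase for r in cohort.subjects[0].records]
        assert phases == ["baseline", "gameplay", "gameplay", "gameplay"]

    def test_study_scale_cohort_counts(self):
        cohort = make_cohort(ScenarioConfig(), (15, 30, 23, 2), seed=1,
                             render=False)
        assert len(cohort.subjects) == 70
        assert cohort.n_records == 280

    def test_iat_scores_fall_in_class_bands(self):
        cohort = make_cohort(ScenarioConfig(), (3, 3, 3, 3), seed=2,
                             render=False)
        for s in cohort.subjects:
            lo, hi = IAT_BANDS[s.severity]
            assert lo <= s.iat_score <= hi

    def test_manifest_deterministic_under_seed(self):
        a = make_cohort(ScenarioConfig(), (2, 1, 0, 0), seed=3, render=False)
        b = make_cohort(ScenarioConfig(), (2, 1, 0, 0), seed=3, render=False)
        assert a.manifest() == b.manifest()

    def test_gameplay_records_are_long_enough_for_28_windows(self, tiny_cohort):
        for rec in tiny_cohort.subjects[0].records:
            if rec.phase == "gameplay":
                assert rec.duration >= 300.0
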