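"""Respiration extraction (direct, BB, AM, FM), breath detection, IBrI/BR."""

import numpy as np
import pytest
from scipy import stats

import biozkit as bz

from conftest import dominant_frequency


def _mod_dominant_freq(mod):
    return dominant_frequency(mod.value, mod.resample_hz)


class TestExtractBB:
    def test_recovers_baseline_wander_frequency_and_amplitude(self):
        cfg = bz.SimulationConfig(
            duration=300.0, seed=31,
            respiratory=bz.RespiratoryParams(rate_brpm=15, bb_amplitude=50.0))
        rec = bz.synthesize_record(cfg)
        mod = bz.extract_bb(rec.bioz_real, rec.fs)
        assert abs(_mod_dominant_freq(mod) - 0.25) < 0.02
        # amplitude of the dominant oscillation within 15% of 50 mOhm
        trim = mod.value[int(10 * mod.resample_hz):-int(10 * mod.resample_hz)]
        amp = np.sqrt(2) * np.std(trim)
        assert abs(amp - 50.0) < 0.15 * 50.0

    def test_no_baseline_modulation_gives_small_bb(self):
        mk = lambda bb: bz.synthesize_record(bz.SimulationConfig(
            duration=180.0, seed=32, noise_sd=0.0,
            respiratory=bz.RespiratoryParams(rate_brpm=15, bb_amplitude=bb,
                                             am_depth=0.2)))
        with_bb = bz.extract_bb(mk(50.0).bioz_real, 250.0)
        without = bz.extract_bb(mk(0.0).bioz_real, 250.0)
        rms = lambda m: np.sqrt(np.mean(m.value ** 2))
        assert rms(without) < 0.1 * rms(with_bb)

    def test_constant_channel_gives_zero(self):
        mod = bz.extract_bb(np.full(250 * 120, 5.0), 250.0)
        assert np.abs(mod.value).max() < 1e-6


class TestExtractAM:
    def _record(self, am_depth, seed=33):
        return bz.synthesize_record(bz.SimulationConfig(
            duration=300.0, seed=seed,
            respiratory=bz.RespiratoryParams(rate_brpm=15,
                                             am_depth=am_depth)))

    def _am(self, rec):
        hf = bz.bandpass(rec.bioz_real, rec.fs, bz.HF_SPEC)
        beats = bz.detect_bioz_beats(hf, rec.fs)
        return bz.extract_am(hf, rec.fs, beats)

    def test_am_series_oscillates_at_breathing_rate(self):
        mod = self._am(self._record(0.2))
        assert abs(_mod_dominant_freq(mod) - 0.25) < 0.02

    def test_unmodulated_amplitude_gives_floor_level_am(self):
        rms = lambda m: np.sqrt(np.mean(m.value ** 2))
        assert rms(self._am(self._record(0.0))) \
            < 0.1 * rms(self._am(self._record(0.2)))

    def test_too_few_beats_raises(self):
        beats = bz.EventSeries(times=np.array([0.0, 1.0]), kind="beat")
        with pytest.raises(ValueError):
            bz.extract_am(np.zeros(2500), 250.0, beats)


class TestExtractFM:
    def _fm(self, rsa, jitter=0.0, seed=34):
        rec = bz.synthesize_record(bz.SimulationConfig(
            duration=300.0, seed=seed,
            cardiac=bz.CardiacParams(rsa_depth=rsa, ibi_jitter_sd=jitter),
            respiratory=bz.RespiratoryParams(rate_brpm=15)))
        hf = bz.bandpass(rec.bioz_real, rec.fs, bz.HF_SPEC)
        beats = bz.detect_bioz_beats(hf, rec.fs)
        return bz.extract_fm(beats, duration=rec.duration)

    def test_rsa_recovered_at_breathing_rate_with_expected_depth(self):
        mod = self._fm(rsa=0.05)
        assert abs(_mod_dominant_freq(mod) - 0.25) < 0.02
        trim = mod.value[int(10 * mod.resample_hz):-int(10 * mod.resample_hz)]
        amp = np.sqrt(2) * np.std(trim)
        assert abs(amp - 0.05) < 0.3 * 0.05

    def test_no_rsa_gives_only_jitter_floor(self):
        rms = lambda m: np.sqrt(np.mean(m.value ** 2))
        jitter_only = rms(self._fm(rsa=0.0, jitter=0.02))
        with_rsa = rms(self._fm(rsa=0.05, jitter=0.02))
        assert jitter_only < with_rsa
        assert rms(self._fm(rsa=0.0, jitter=0.0)) < 0.1 * with_rsa

    def test_regular_beats_give_near_zero_fm(self):
        beats = bz.EventSeries(times=np.arange(0.0, 120.0, 0.8), kind="beat")
        mod = bz.extract_fm(beats, duration=120.0)
        assert np.abs(mod.value).max() < 1e-6


class TestExtractDirect:
    def test_direct_series_tracks_belt(self):
        rec = bz.synthesize_record(bz.SimulationConfig(
            duration=240.0, seed=35, noise_sd=0.0,
            morphology=bz.site_morphology("ribcage"),
            respiratory=bz.RespiratoryParams(rate_brpm=15,
                                             bb_amplitude=200.0)))
        mod = bz.extract_direct(rec, "real")
        belt_on_grid = np.interp(mod.t, rec.t, rec.belt)
        sl = slice(int(20 * mod.resample_hz), -int(20 * mod.resample_hz))
        r = stats.pearsonr(mod.value[sl], belt_on_grid[sl]).statistic
        assert r >= 0.95

    def test_imaginary_component_shares_dominant_frequency(
            self, thoracic_record):
        f_re = _mod_dominant_freq(bz.extract_direct(thoracic_record, "real"))
        f_im = _mod_dominant_freq(
            bz.extract_direct(thoracic_record, "imaginary"))
        assert abs(f_re - f_im) < 0.01

    def test_slow_breathing_config(self):
        rec = bz.synthesize_record(bz.SimulationConfig(
            duration=240.0, seed=36, noise_sd=10.0,
            morphology=bz.site_morphology("ribcage"),
            respiratory=bz.RespiratoryParams(rate_brpm=12,
                                             bb_amplitude=200.0)))
        mod = bz.extract_direct(rec, "real")
        assert abs(_mod_dominant_freq(mod) - 0.2) < 0.02

    def test_arterial_site_warns(self, radial_record):
        with pytest.warns(UserWarning, match="off-design"):
            bz.extract_direct(radial_record, "real")


class TestDetectBreaths:
    def test_pure_sinusoid_peak_count_and_spacing(self):
        t = np.arange(0.0, 60.0, 0.25)
        mod = bz.ModulationSeries(kind="direct", t=t,
                                  value=np.sin(2 * np.pi * 0.25 * t),
                                  resample_hz=4.0)
        ev = bz.detect_breaths(mod)
        assert len(ev) == 15
        np.testing.assert_allclose(ev.intervals, 4.0, atol=0.05)

    def test_subthreshold_ripples_rejected_by_prominence(self):
        t = np.arange(0.0, 120.0, 0.25)
        clean = np.sin(2 * np.pi * 0.2 * t)
        rippled = clean + 0.05 * np.sin(2 * np.pi * 0.45 * t)
        ev = bz.detect_breaths(bz.ModulationSeries(
            kind="direct", t=t, value=rippled, resample_hz=4.0))
        ref = bz.detect_breaths(bz.ModulationSeries(
            kind="direct", t=t, value=clean, resample_hz=4.0))
        assert len(ev) == len(ref)

    def test_belt_peaks_match_truth(self, thoracic_record):
        rec = thoracic_record
        mod = bz.ModulationSeries(kind="direct", t=rec.t, value=rec.belt,
                                  resample_hz=rec.fs)
        ev = bz.detect_breaths(mod)
        m = bz.match_events(ev, rec.truth_breaths, 1.0)
        assert np.abs(m.event_pairs[:, 0] - m.event_pairs[:, 1]).max() < 0.1

    def test_flat_series_raises(self):
        mod = bz.ModulationSeries(kind="BB", t=np.arange(0, 30, 0.25),
                                  value=np.zeros(120), resample_hz=4.0)
        with pytest.raises(ValueError):
            bz.detect_breaths(mod)


class TestBreathingRate:
    @pytest.mark.parametrize("spacing, expected", [(4.0, 15.0), (5.0, 12.0)])
    def test_uniform_peaks(self, spacing, expected):
        ev = bz.EventSeries(times=np.arange(0.0, 60.0, spacing),
                            kind="breath")
        assert bz.breathing_rate(ev) == pytest.approx(expected)

    def test_single_breath_raises(self):
        with pytest.raises(ValueError):
            bz.breathing_rate(bz.EventSeries(times=np.array([3.0]),
                                             kind="breath"))

    def test_estimate_within_one_brpm_at_default_noise(self):
        rec = bz.synthesize_record(bz.SimulationConfig(
            duration=300.0, seed=37,
            respiratory=bz.RespiratoryParams(rate_brpm=16)))
        rep = bz.analyze_respiration(rec, "BB")
        assert abs(rep.rate_brpm - 16.0) <= 1.0


class TestCrossModalityProperties:
    def test_all_indirect_modalities_share_dominant_frequency(
            self, radial_record, radial_hf, radial_beats):
        rec = radial_record
        f_bb = _mod_dominant_freq(bz.extract_bb(rec.bioz_real, rec.fs))
        f_am = _mod_dominant_freq(
            bz.extract_am(radial_hf, rec.fs, radial_beats))
        f_fm = _mod_dominant_freq(
            bz.extract_fm(radial_beats, duration=rec.duration))
        target = rec.config.respiratory.freq_hz
        for f in (f_bb, f_am, f_fm):
            assert abs(f - target) < 0.02

    def test_ibri_error_shrinks_with_noise(self):
        maes = []
        for noise in (40.0, 10.0, 0.0):
            rec = bz.synthesize_record(bz.SimulationConfig(
                duration=240.0, seed=38, noise_sd=noise,
                morphology=bz.site_morphology("ribcage"),
                respiratory=bz.RespiratoryParams(rate_brpm=15,
                                                 bb_amplitude=200.0)))
            rep = bz.analyze_respiration(rec, "direct")
            m = bz.match_events(rep.events, rec.truth_breaths, 1.0)
            maes.append(np.sqrt(np.mean((m.est - m.ref) ** 2)))
        assert maes[0] >= maes[1] >= maes[2]
        assert maes[2] < 0.1

    def test_breath_times_stable_under_resample_doubling(self, radial_record):
        rec = radial_record
        ev4 = bz.detect_breaths(bz.extract_bb(rec.bioz_real, rec.fs, 4.0))
        ev8 = bz.detect_breaths(bz.extract_bb(rec.bioz_real, rec.fs, 8.0))
        m = bz.match_events(ev4, ev8, 0.5)
        assert np.abs(m.event_pairs[:, 0] - m.event_pairs[:, 1]).max() < 0.05
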