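"""Acoustic stimulus preparation on synthetic audio."""

import numpy as np
import pytest

from dintest.stimuli import (
    AudioClip, ExemplarStats, LtassConfig, apply_filter,
    design_correction_filter, equalize_level, estimate_f0, ltass,
    select_by_f0, select_exemplars, speech_shaped_noise,
    synthetic_digit_token,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


def _band(spec, lo, hi):
    m = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    return spec.levels_db[m]


class TestLtass:
    def test_white_noise_is_flat(self, rng):
        clip = AudioClip(rng.standard_normal(44100 * 4))
        spec = ltass(clip)
        band = _band(spec, 200, 8000)
        assert band.max() - band.min() < 3.0  # dB, estimation error only

    def test_speech_shaped_slope_recovered(self, rng):
        """-6 dB/octave above 500 Hz: levels at 1 and 4 kHz differ ~12 dB."""
        clip = speech_shaped_noise(8.0, rng)
        spec = ltass(clip)
        l1k = _band(spec, 950, 1050).mean()
        l4k = _band(spec, 3800, 4200).mean()
        assert (l1k - l4k) == pytest.approx(12.0, abs=2.0)

    def test_sine_peaks_at_its_frequency(self, rng):
        t = np.arange(44100 * 2) / 44100
        clip = AudioClip(np.sin(2 * np.pi * 1000 * t))
        spec = ltass(clip, LtassConfig(third_octave_smooth=False))
        peak = spec.freqs_hz[np.argmax(spec.levels_db)]
        assert peak == pytest.approx(1000, abs=50)

    def test_short_clip_rejected(self, rng):
        with pytest.raises(ValueError):
            ltass(AudioClip(rng.standard_normal(1000)))


class TestCorrectionFilter:
    def test_identical_spectra_give_unity_filter(self, rng):
        spec = ltass(speech_shaped_noise(4.0, rng))
        taps = design_correction_filter(spec, spec)
        w = np.fft.rfft(taps, 8192)
        mag_db = 20 * np.log10(np.abs(w) + 1e-12)
        f = np.fft.rfftfreq(8192, 1 / 44100)
        m = (f > 100) & (f < 8000)
        assert np.abs(mag_db[m]).max() < 1.0

    def test_round_trip_matches_reference_within_tolerance(self, rng):
        """Filtering a tilted talker brings its LTASS within ~2 dB of the
        reference across 100 Hz - 8 kHz."""
        ref_clip = speech_shaped_noise(8.0, rng, slope_db_per_octave=-6.0)
        talker_clip = speech_shaped_noise(8.0, rng, slope_db_per_octave=-9.0)
        ref, talker = ltass(ref_clip), ltass(talker_clip)
        taps = design_correction_filter(talker, ref)
        corrected = ltass(apply_filter(talker_clip, taps))
        m = (ref.freqs_hz >= 100) & (ref.freqs_hz <= 8000)
        err_before = np.abs(talker.levels_db[m] - ref.levels_db[m])
        err_after = np.abs(corrected.levels_db[m] - ref.levels_db[m])
        assert err_after.max() < err_before.max()  # contraction
        assert np.percentile(err_after, 95) < 2.0

    def test_mismatched_grids_rejected(self, rng):
        a = ltass(speech_shaped_noise(2.0, rng))
        b = ltass(speech_shaped_noise(2.0, rng), LtassConfig(window_samples=512))
        with pytest.raises(ValueError):
            design_correction_filter(a, b)


class TestExemplarSelection:
    def test_identical_exemplars_all_retained(self):
        stats = ExemplarStats(
            level_db={f"e{i}": -23.0 for i in range(6)},
            duration_ms={f"e{i}": 500.0 for i in range(6)},
            digit_of={f"e{i}": 3 for i in range(6)})
        assert len(select_exemplars(stats)[3]) == 6

    def test_planted_outliers_removed(self, rng):
        """24 exemplars, 4 planted far outliers -> exactly 20 retained."""
        levels = {f"e{i}": -23.0 + float(rng.normal(0, 0.3)) for i in range(24)}
        durs = {f"e{i}": 500.0 + float(rng.normal(0, 5.0)) for i in range(24)}
        for k in ("e0", "e1"):
            levels[k] = -5.0       # level outliers
        for k in ("e2", "e3"):
            durs[k] = 900.0        # duration outliers
        stats = ExemplarStats(level_db=levels, duration_ms=durs,
                              digit_of={k: 8 for k in levels})
        kept = select_exemplars(stats)[8]
        assert len(kept) == 20
        assert not {"e0", "e1", "e2", "e3"} & set(kept)

    def test_f0_selection_picks_near_median(self, rng):
        clips = {}
        f0s = [120, 170, 175, 180, 185, 190, 240, 175, 182, 178]
        for i, f0 in enumerate(f0s):
            clips[f"e{i}"] = synthetic_digit_token(rng, f0_hz=f0)
        chosen = select_by_f0(clips, list(clips), n_final=6)
        assert len(chosen) == 6
        assert "e0" not in chosen and "e6" not in chosen  # extremes dropped


class TestLevelEqualization:
    def test_two_clips_meet_at_mean_level(self, rng):
        a = synthetic_digit_token(rng, level_db=-20.0)
        b = synthetic_digit_token(rng, level_db=-26.0)
        out = equalize_level([a, b])
        assert out[0].rms_db() == pytest.approx(-23.0, abs=1e-9)
        assert out[1].rms_db() == pytest.approx(-23.0, abs=1e-9)

    def test_already_equal_clips_unchanged(self, rng):
        a = synthetic_digit_token(rng, level_db=-23.0)
        out = equalize_level([a, a])
        np.testing.assert_allclose(out[0].samples, a.samples, atol=1e-12)

    def test_gain_only_preserves_duration(self, rng):
        a = synthetic_digit_token(rng, duration_ms=480, level_db=-30.0)
        out = equalize_level([a, synthetic_digit_token(rng, level_db=-20.0)])
        assert out[0].duration_ms == a.duration_ms

    def test_silent_clip_rejected(self):
        with pytest.raises(ValueError):
            equalize_level([AudioClip(np.zeros(100))])


class TestTokensAndIo:
    def test_token_hits_requested_level_and_duration(self, rng):
        tok = synthetic_digit_token(rng, duration_ms=450, level_db=-25.0,
                                    f0_hz=200.0)
        assert tok.rms_db() == pytest.approx(-25.0, abs=1e-6)
        assert tok.duration_ms == pytest.approx(450, abs=1)

    def test_f0_estimate_recovers_periodicity(self, rng):
        tok = synthetic_digit_token(rng, f0_hz=180.0)
        assert estimate_f0(tok) == pytest.approx(180.0, rel=0.08)

    def test_wav_roundtrip_16bit(self, rng, tmp_path):
        tok = synthetic_digit_token(rng)
        p = tmp_path / "tok.wav"
        tok.save(p)
        back = AudioClip.load(p)
        assert back.rate == 44100
        np.testing.assert_allclose(back.samples, np.clip(tok.samples, -1, 1),
                                   atol=1.0 / 32000)
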