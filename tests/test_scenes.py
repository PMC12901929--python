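"""Scene synthesis: sources, spatialization, calibration, I/O."""

import numpy as np
import pytest
from scipy import signal as sps

import bsim
from bsim.scenes import SpatializerConfig, save_scene, load_scene
from bsim.signals import MonoSignal

FS = 22050.0


def octave_band_levels(x: np.ndarray, fs: float, centers=(250, 500, 1000, 2000, 4000)) -> np.ndarray:
    f, psd = sps.welch(x, fs=fs, nperseg=int(fs * 0.2))
    out = []
    for fc in centers:
        sel = (f >= fc / np.sqrt(2)) & (f < fc * np.sqrt(2))
        out.append(10 * np.log10(np.trapezoid(psd[sel], f[sel])))
    return np.array(out)


def envelope_modulation_spectrum(x: np.ndarray, fs: float):
    env = np.abs(sps.hilbert(x))
    env = env - env.mean()
    f, psd = sps.welch(env, fs=fs, nperseg=int(fs * 1.0))
    return f, psd


class TestSpeechLikeSignal:
    def test_seeded_determinism(self):
        a = bsim.make_speech_like_signal(1.5, 42, FS)
        b = bsim.make_speech_like_signal(1.5, 42, FS)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_same_long_term_spectrum(self):
        a = bsim.make_speech_like_signal(4.0, 1, FS)
        b = bsim.make_speech_like_signal(4.0, 2, FS)
        assert not np.allclose(a.samples, b.samples)
        la = octave_band_levels(a.samples, FS)
        lb = octave_band_levels(b.samples, FS)
        assert np.max(np.abs(la - lb)) < 1.0

    def test_modulation_peak_in_syllabic_range(self):
        s = bsim.make_speech_like_signal(4.0, 3, FS)
        f, psd = envelope_modulation_spectrum(s.samples, FS)
        sel = (f >= 0.5) & (f <= 64.0)
        peak = f[sel][np.argmax(psd[sel])]
        assert 2.0 <= peak <= 8.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            bsim.make_speech_like_signal(0.5, 0, FS)


class TestStationaryMasker:
    def test_flat_reference_gives_flat_masker(self, rng):
        white = MonoSignal(rng.standard_normal(int(FS * 2)), FS)
        m = bsim.make_stationary_masker(white, 2.0, 5)
        lv = octave_band_levels(m.samples, FS)
        # flat spectrum => equal energy per octave after removing the 3 dB/oct trend
        trend = 10 * np.log10([250, 500, 1000, 2000, 4000])
        resid = (lv - trend) - np.mean(lv - trend)
        assert np.max(np.abs(resid)) < 1.0

    def test_octave_levels_match_speech_reference(self):
        s = bsim.make_speech_like_signal(4.0, 1, FS)
        m = bsim.make_stationary_masker(s, 4.0, 2, level_db_spl=s.level_db_spl)
        assert np.max(np.abs(octave_band_levels(m.samples, FS) - octave_band_levels(s.samples, FS))) < 1.0

    def test_masker_is_stationary(self):
        s = bsim.make_speech_like_signal(4.0, 1, FS)
        m = bsim.make_stationary_masker(s, 4.0, 2)

        def mod_index(x):
            env = np.abs(sps.hilbert(x))
            sos = sps.butter(2, 32.0, fs=FS, output="sos")
            env = sps.sosfiltfilt(sos, env)
            return np.std(env) / np.mean(env)

        assert mod_index(m.samples) < 0.5 * mod_index(s.samples)


class TestSpatialize:
    def test_frontal_is_diotic(self):
        s = bsim.make_speech_like_signal(1.0, 0, FS)
        out = bsim.spatialize(s, 0)
        np.testing.assert_array_equal(out.left.samples, out.right.samples)

    def test_itd_of_lateral_tone(self):
        cfg = SpatializerConfig()
        t = np.arange(int(FS)) / FS
        tone = MonoSignal(np.sin(2 * np.pi * 500 * t), FS)
        out = bsim.spatialize(tone, 90, cfg)  # source right: left ear lags
        spec_l = np.fft.rfft(out.left.samples)
        spec_r = np.fft.rfft(out.right.samples)
        k = int(round(500 * tone.n_samples / FS))
        phase = np.angle(spec_l[k] / spec_r[k])
        measured_itd = -phase / (2 * np.pi * 500)
        assert abs(measured_itd - cfg.itd_at_90deg) < 2e-6

    def test_ild_at_4khz(self, rng):
        cfg = SpatializerConfig()
        broadband = MonoSignal(rng.standard_normal(int(FS * 2)), FS)
        out = bsim.spatialize(broadband, 90, cfg)
        lv_r = octave_band_levels(out.right.samples, FS, centers=(4000,))
        lv_l = octave_band_levels(out.left.samples, FS, centers=(4000,))
        assert abs((lv_r - lv_l)[0] - cfg.ild_db(np.array([4000.0]))[0]) < 0.5

    def test_energy_conserved_at_ipsilateral_ear(self):
        s = bsim.make_speech_like_signal(1.0, 0, FS)
        out = bsim.spatialize(s, -90)  # source left: left is direct
        assert abs(out.left.level_db_spl - s.level_db_spl) < 0.1

    def test_unsupported_azimuth(self):
        s = bsim.make_speech_like_signal(1.0, 0, FS)
        with pytest.raises(ValueError):
            bsim.spatialize(s, 45)


class TestBuildScene:
    @pytest.fixture(scope="class")
    def sources(self):
        s = bsim.make_speech_like_signal(1.0, 1, FS)
        n = bsim.make_stationary_masker(s, 1.0, 2)
        return s, n

    def test_s0n0_levels_and_diotic(self, sources):
        s, n = sources
        scene = bsim.build_scene(s, n, "S0N0", "left", 0.0)
        assert abs(scene.speech.left.level_db_spl - scene.noise.left.level_db_spl) < 0.01
        np.testing.assert_array_equal(scene.speech.left.samples, scene.speech.right.samples)
        np.testing.assert_array_equal(scene.noise.left.samples, scene.noise.right.samples)

    def test_monaural_gating(self, sources):
        s, n = sources
        scene = bsim.build_scene(s, n, "S0mN90m", "left", -3.0)
        assert np.all(scene.speech.left.samples == 0.0)
        assert np.all(scene.noise.left.samples == 0.0)
        assert np.any(scene.noise.right.samples != 0.0)

    def test_s0n90_better_ear_snr_margin(self, sources):
        s, n = sources
        scene = bsim.build_scene(s, n, "S0N90", "left", 0.0)
        # noise toward the worse (left) ear: better-ear (right) SNR must win
        def snr(ear):
            return scene.speech.channel(ear).level_db_spl - scene.noise.channel(ear).level_db_spl

        margin = snr("right") - snr("left")
        assert margin > 0.0
        # band-level oracle: expected broadband shadow from the ILD profile
        f, psd = sps.welch(scene.noise.left.samples, fs=FS, nperseg=int(FS * 0.2))
        att = 10.0 ** (-scene.config.ild_db(f) / 10.0)
        expected = -10.0 * np.log10(np.trapezoid(psd * att, f) / np.trapezoid(psd, f))
        assert margin == pytest.approx(expected, abs=0.5)

    def test_rescaling_preserves_snr(self, sources):
        s, n = sources
        scene = bsim.build_scene(s, n, "S0N0", "left", 4.0)
        sp = scene.speech.scaled_by(7.0)
        no = scene.noise.scaled_by(7.0)
        assert abs((sp.left.level_db_spl - no.left.level_db_spl) - 4.0) < 0.01

    def test_sample_rate_mismatch(self, sources):
        s, _ = sources
        other = bsim.make_speech_like_signal(1.0, 1, 32000.0)
        with pytest.raises(ValueError):
            bsim.build_scene(s, other, "S0N0", "left", 0.0)

    def test_wav_roundtrip(self, sources, tmp_path):
        s, n = sources
        scene = bsim.build_scene(s, n, "S0N90", "right", -6.0)
        save_scene(scene, tmp_path / "sc")
        back = load_scene(tmp_path / "sc")
        assert back.condition == "S0N90" and back.worse_ear == "right"
        assert back.snr_db == pytest.approx(-6.0)
        # float32 storage round-trip
        np.testing.assert_allclose(back.noise.left.samples, scene.noise.left.samples, atol=1e-6)
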