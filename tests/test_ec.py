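"""Blind EC front-end: equalization, cancellation, jitter, SRMR selection."""

import numpy as np
import pytest

from bsim.ec import (
    ECConfig,
    JitterConfig,
    SRMRConfig,
    apply_disposition,
    apply_jitter,
    cancel,
    ec_process,
    equalize,
    fractional_delay,
    select_better_ear,
    select_strategy,
    srmr,
)
from bsim.periphery import BandSignals, band_center_frequencies, gammatone_analyze_mono

FS = 22050.0


def band_noise(seed: int, band: int = 6, duration: float = 1.0) -> np.ndarray:
    x = np.random.default_rng(seed).standard_normal(int(FS * duration))
    return gammatone_analyze_mono(x, FS)[band]


class TestEqualize:
    def test_constructed_delay(self):
        l = band_noise(0)
        r = fractional_delay(l, 500e-6, FS)
        d, g, degen = equalize(l, r, FS)
        assert not degen
        assert d == pytest.approx(500e-6, abs=10e-6)
        assert g == pytest.approx(0.0, abs=0.1)

    def test_constructed_gain(self):
        l = band_noise(1)
        r = l * 10 ** (-6 / 20)
        d, g, _ = equalize(l, r, FS)
        assert g == pytest.approx(-6.0, abs=0.1)
        assert d == pytest.approx(0.0, abs=5e-6)

    def test_silent_band_degenerate(self):
        d, g, degen = equalize(np.zeros(4096), np.zeros(4096), FS)
        assert (d, g, degen) == (0.0, 0.0, True)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_residual_search(self, seed):
        """(delay, gain) agree with exhaustive residual-power minimization."""
        rng = np.random.default_rng(seed)
        l = band_noise(seed + 10)
        true_d = rng.uniform(-1e-3, 1e-3)
        true_g = rng.uniform(-6.0, 6.0)
        r = fractional_delay(l, true_d, FS) * 10 ** (true_g / 20)
        r += 0.01 * band_noise(seed + 50)  # slight decorrelation
        d_est, g_est, _ = equalize(l, r, FS)

        # oracle: integer-sample delay grid x 0.25 dB gain grid
        delay_grid = np.arange(-44, 45)
        gain_grid = np.arange(-8.0, 8.01, 0.25)
        best = (None, None, np.inf)
        for lag in delay_grid:
            r_adv = np.roll(r, -lag)
            for gg in gain_grid:
                resid = np.mean((l - r_adv * 10 ** (-gg / 20)) ** 2)
                if resid < best[2]:
                    best = (lag / FS, gg, resid)
        assert d_est == pytest.approx(best[0], abs=1.0 / FS)
        assert g_est == pytest.approx(best[1], abs=0.25)


class TestCancel:
    def test_identical_minimize_cancels(self):
        l = band_noise(2)
        out = cancel(l, l.copy(), 0.0, 0.0, "minimize", FS)
        assert np.mean(out**2) <= 1e-6 * np.mean(l**2)

    def test_identical_maximize_is_identity(self):
        l = band_noise(3)
        out = cancel(l, l.copy(), 0.0, 0.0, "maximize", FS)
        np.testing.assert_allclose(out, l, atol=1e-12)

    def test_antiphasic_noise_split_between_pathways(self):
        """Diotic speech + antiphasic noise at zero equalization: the sum
        pathway returns the clean speech, the difference pathway the noise."""
        sp = band_noise(4)
        no = band_noise(5)
        l, r = sp + no, sp - no
        np.testing.assert_allclose(cancel(l, r, 0.0, 0.0, "maximize", FS), sp, atol=1e-10)
        np.testing.assert_allclose(cancel(l, r, 0.0, 0.0, "minimize", FS), no, atol=1e-10)


class TestJitter:
    def test_zero_sd_identity(self, rng):
        assert apply_jitter(1e-4, 2.0, JitterConfig.off(), rng) == (1e-4, 2.0)

    def test_sample_sd_matches_config(self, rng):
        cfg = JitterConfig(delay_jitter_sd_s=65e-6, gain_jitter_sd_db=1.5)
        draws = np.array([apply_jitter(0.0, 0.0, cfg, rng) for _ in range(10_000)])
        assert np.std(draws[:, 0]) == pytest.approx(65e-6, rel=0.05)
        assert np.std(draws[:, 1]) == pytest.approx(1.5, rel=0.05)

    def test_jitter_degrades_cancellation(self, rng):
        l = band_noise(6)
        d, g = apply_jitter(0.0, 0.0, JitterConfig(), rng)
        p_jit = np.mean(cancel(l, l.copy(), d, g, "minimize", FS) ** 2)
        p_opt = np.mean(cancel(l, l.copy(), 0.0, 0.0, "minimize", FS) ** 2)
        assert p_jit > p_opt


class TestSRMR:
    @staticmethod
    def modulated_noise(fm: float, seed: int = 0, duration: float = 2.0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        t = np.arange(int(FS * duration)) / FS
        carrier = rng.standard_normal(t.size)
        return carrier * (1.0 + 0.8 * np.sin(2 * np.pi * fm * t))

    def test_slow_modulation_scores_higher_than_none(self):
        mod = self.modulated_noise(4.0)
        unmod = np.random.default_rng(0).standard_normal(mod.size)
        assert srmr(mod, FS) > srmr(unmod, FS)

    def test_scale_invariance(self):
        x = self.modulated_noise(4.0, seed=1)
        assert srmr(2.0 * x, FS) == pytest.approx(srmr(x, FS), rel=1e-6)

    def test_fast_modulation_scores_lower(self):
        assert srmr(self.modulated_noise(64.0), FS) < srmr(self.modulated_noise(4.0), FS)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            srmr(np.zeros(1000), FS)


class TestSelection:
    def test_speechlike_beats_stationary(self):
        speechy = TestSRMR.modulated_noise(4.0, seed=2)
        flat = np.random.default_rng(3).standard_normal(speechy.size)
        assert select_strategy(speechy, flat, FS) == "minimize"
        assert select_strategy(flat, speechy, FS) == "maximize"

    def test_tie_prefers_minimize(self):
        x = TestSRMR.modulated_noise(4.0, seed=4)
        assert select_strategy(x, x.copy(), FS) == "minimize"

    def test_better_ear_tie_prefers_left(self):
        x = TestSRMR.modulated_noise(4.0, seed=5)
        assert select_better_ear(x, x.copy(), FS) == "left"

    def test_better_ear_prefers_modulated(self):
        speechy = TestSRMR.modulated_noise(4.0, seed=6)
        flat = np.random.default_rng(7).standard_normal(speechy.size)
        assert select_better_ear(flat, speechy, FS) == "right"

    def test_silent_ear_loses(self):
        x = TestSRMR.modulated_noise(4.0, seed=8)
        assert select_better_ear(np.zeros_like(x), x, FS) == "right"
        assert select_better_ear(x, np.zeros_like(x), FS) == "left"


def _make_bands(left: np.ndarray, right: np.ndarray) -> BandSignals:
    return BandSignals(
        center_frequencies=band_center_frequencies(),
        left=left,
        right=right,
        sample_rate=FS,
    )


class TestECProcess:
    @pytest.fixture(scope="class")
    def mixture_bands(self):
        rng = np.random.default_rng(11)
        x_l = rng.standard_normal(int(FS))
        x_r = rng.standard_normal(int(FS))
        return _make_bands(
            gammatone_analyze_mono(x_l, FS), gammatone_analyze_mono(x_r, FS)
        )

    def test_monaural_bypass(self, mixture_bands):
        bands = _make_bands(mixture_bands.left, np.zeros_like(mixture_bands.left))
        mono, params = ec_process(bands, ECConfig(n_monte_carlo=2))
        assert params.monaural_ear == "left"
        assert all(d.selected_ear == "left" for d in params.bands)
        np.testing.assert_array_equal(mono.left, bands.left)

    def test_every_band_has_one_disposition(self, mixture_bands):
        _, params = ec_process(mixture_bands, ECConfig(n_monte_carlo=3), JitterConfig())
        cf = band_center_frequencies()
        for fc, disp in zip(cf, params.bands):
            if fc < 1500.0:
                assert disp.strategy in ("minimize", "maximize")
                assert disp.selected_ear is None
                assert len(disp.jittered) == 3
            else:
                assert disp.selected_ear in ("left", "right")
                assert disp.strategy is None

    def test_linearity_of_frozen_dispositions(self, mixture_bands):
        """Processing a sum of scenes equals the sum of processed scenes."""
        _, params = ec_process(mixture_bands, ECConfig(n_monte_carlo=1), JitterConfig())
        rng = np.random.default_rng(12)
        a = _make_bands(
            gammatone_analyze_mono(rng.standard_normal(int(FS)), FS),
            gammatone_analyze_mono(rng.standard_normal(int(FS)), FS),
        )
        b = _make_bands(
            gammatone_analyze_mono(rng.standard_normal(int(FS)), FS),
            gammatone_analyze_mono(rng.standard_normal(int(FS)), FS),
        )
        ab = _make_bands(a.left + b.left, a.right + b.right)
        out_sum = apply_disposition(ab, params, draw=0).left
        sum_out = apply_disposition(a, params, draw=0).left + apply_disposition(b, params, draw=0).left
        assert np.linalg.norm(out_sum - sum_out) <= 1e-9 * np.linalg.norm(out_sum)

    def test_jitter_off_deep_cancellation(self):
        """Identical ears + minimize: essentially perfect noise removal."""
        rng = np.random.default_rng(13)
        x = gammatone_analyze_mono(rng.standard_normal(int(FS)), FS)
        bands = _make_bands(x, x.copy())
        cfg = ECConfig(n_monte_carlo=1)
        _, params = ec_process(bands, cfg, JitterConfig.off())
        below = [i for i, fc in enumerate(band_center_frequencies()) if fc < 1500.0]
        for i in below:
            out = cancel(bands.left[i], bands.right[i], params.bands[i].delay_s,
                         params.bands[i].gain_db, "minimize", FS)
            assert 10 * np.log10(np.mean(bands.left[i] ** 2) / max(np.mean(out**2), 1e-300)) >= 40.0
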