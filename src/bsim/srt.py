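"""SRT solver: SNR sweep, SII averaging, threshold crossing, individualization.

For one listener and spatial condition the engine sweeps the SNR grid
(-20..+20 dB in 1-dB steps by default), builds the calibrated scene at each
grid point (noise fixed at 65 dB SPL, speech varied), runs the periphery,
blind EC front-end and shadow-filtered SII for every sentence token and
Monte-Carlo jitter draw, and averages the SII values.  The SRT is the first
upward crossing of the mean SII through the reference value (0.2 without
individualization), linearly interpolated on the grid; Monte-Carlo
non-monotonicity is removed by a cumulative maximum before solving.

Individual suprathreshold component (ISC) schemes:

* ``isc_sii``   -- the reference SII becomes the curve value at the listener's
  measured S0N0 SRT; S0N0 is thereby fitted, the spatial conditions are
  predicted with the individual reference.
* ``isc_noise`` -- the external masker is raised by max(0, measured - predicted)
  dB in every condition; the reference stays 0.2 and SRTs are still reported
  relative to the nominal 65 dB SPL noise (this scheme can only shift
  predictions upward).

Implementation note: the sweep runs on a band-domain cache.  Because every
front-end disposition is a linear operator (circular fractional delay, scalar
gain, sum/difference, ear pick), shadow-filtered band powers are evaluated
exactly from cached band spectra and cross-spectra instead of re-filtering
waveforms at every grid point; strategy and better-ear selection use the
jitter-free EC outputs reconstructed from cached analytic signals.  The
time-domain path in :mod:`bsim.ec`/:mod:`bsim.sii` is the reference
implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from . import scenes as sc
from .cohort import Listener
from .ec import ECConfig, JitterConfig, SRMRConfig, parabolic_argmax
from .periphery import TSNConfig, band_center_frequencies, gammatone_analyze_mono, make_tsn
from .sii import SIIConfig, sii

CONDITIONS = sc.CONDITIONS


@dataclass
class SolverConfig:
    """Sweep and averaging parameters of the SRT solver."""

    snr_min_db: float = -20.0
    snr_max_db: float = 20.0
    snr_step_db: float = 1.0
    n_sentences: int = 10
    n_monte_carlo: int = 10
    reference_sii: float = 0.2
    sample_rate: float = sc.DEFAULT_SAMPLE_RATE
    token_duration: float = sc.DEFAULT_TOKEN_DURATION
    noise_level_db_spl: float = sc.DEFAULT_NOISE_LEVEL_DB_SPL

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_sii < 1.0:
            raise ValueError("reference_sii must lie in (0, 1)")
        if self.snr_step_db <= 0 or self.snr_max_db <= self.snr_min_db:
            raise ValueError("SNR grid must be strictly increasing")

    @property
    def snr_grid(self) -> np.ndarray:
        n = int(round((self.snr_max_db - self.snr_min_db) / self.snr_step_db)) + 1
        return self.snr_min_db + self.snr_step_db * np.arange(n)


@dataclass
class PsychometricCurve:
    """Mean SII versus SNR, with the underlying per-simulation values."""

    snr_grid: np.ndarray
    mean_sii: np.ndarray
    draws: np.ndarray  # (n_snr, n_sentences * n_monte_carlo)
    flags: list = field(default_factory=list)

    def monotone_mean(self) -> np.ndarray:
        """Cumulative-maximum rectified mean curve, made strictly increasing.

        Monte-Carlo wiggle can create flat segments after rectification; an
        infinitesimal slope (1e-9 per grid step) breaks them so the
        reference <-> SRT mapping is invertible, keeping the individual-
        reference calibration an exact round trip.
        """
        m = np.maximum.accumulate(self.mean_sii)
        return m + 1e-9 * np.arange(m.size)


@dataclass
class SRTResult:
    listener_id: str
    condition: str
    method: str
    srt_db: float
    reference_sii_used: float
    noise_increment_db: float = 0.0
    flags: tuple = ()


def solve_srt(curve: PsychometricCurve, reference_sii: float) -> tuple[float, tuple]:
    """First upward crossing of the (monotonized) mean SII through the reference."""
    m = curve.monotone_mean()
    grid = curve.snr_grid
    if m[0] >= reference_sii:
        return float(grid[0]), ("out_of_range_low",)
    if m[-1] < reference_sii:
        return float(grid[-1]), ("out_of_range_high",)
    idx = int(np.searchsorted(m, reference_sii, side="left"))
    x0, x1 = grid[idx - 1], grid[idx]
    y0, y1 = m[idx - 1], m[idx]
    srt = x0 if y1 == y0 else x0 + (reference_sii - y0) * (x1 - x0) / (y1 - y0)
    return float(srt), ()


def isc_sii_reference(curve: PsychometricCurve, measured_s0n0_srt: float) -> tuple[float, tuple]:
    """Individual reference SII: curve value at the listener's measured S0N0 SRT."""
    m = curve.monotone_mean()
    grid = curve.snr_grid
    flags: tuple = ()
    if measured_s0n0_srt < grid[0] or measured_s0n0_srt > grid[-1]:
        flags = ("measured_srt_clamped",)
    ref = float(np.interp(measured_s0n0_srt, grid, m))
    return ref, flags


def isc_noise_increment(measured_s0n0_srt: float, predicted_s0n0_srt: float) -> float:
    """Upward-only external-noise increment: max(0, measured - predicted) dB."""
    return max(0.0, float(measured_s0n0_srt - predicted_s0n0_srt))


# ---------------------------------------------------------------------------
# band-domain sweep engine
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _modulation_sos(env_fs: float, f_min: float, f_max: float, n_filters: int) -> tuple:
    cfg = SRMRConfig(n_filters=n_filters, f_min_hz=f_min, f_max_hz=f_max)
    out = []
    for fc in cfg.center_frequencies:
        lo, hi = fc / np.sqrt(2.0), min(fc * np.sqrt(2.0), 0.45 * env_fs)
        out.append(sps.butter(2, [lo, hi], btype="bandpass", fs=env_fs, output="sos"))
    return tuple(tuple(map(tuple, s)) for s in out)


def _srmr_batch(envs: np.ndarray, env_fs: float, cfg: SRMRConfig) -> np.ndarray:
    """SRMR scores for a stack of envelopes (m, n_env)."""
    bank = _modulation_sos(env_fs, cfg.f_min_hz, cfg.f_max_hz, cfg.n_filters)
    powers = np.empty((envs.shape[0], len(bank)))
    for j, sos in enumerate(bank):
        y = sps.sosfilt(np.asarray(sos), envs, axis=-1)
        powers[:, j] = np.mean(y**2, axis=-1)
    half = cfg.n_filters // 2
    low = powers[:, :half].sum(axis=1)
    high = powers[:, half:].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = low / high
    return np.where(high <= 0.0, np.inf, score)


#: target complex-baseband rate (Hz) for the SRMR envelope path
_BASEBAND_RATE_HZ = 4000.0


class _BandCache:
    """Frozen band-domain representation of one (listener, condition, token).

    Holds, per gammatone band, the quantities from which every front-end and
    back-end evaluation on the SNR grid can be formed exactly: band powers,
    same-ear speech/noise cross powers, interaural cross-correlation windows
    of all four source pairings, and banded cross-spectra for fractional-lag
    cross-power evaluation.  For the SRMR selector the analytic band signals
    are stored as frequency-shifted complex baseband signals at a reduced
    rate -- the frequency shift leaves the envelope magnitude untouched and
    the band-limited decimation only discards far-out filter skirts.  Speech
    enters at unit gain for 65 dB SPL free-field and is rescaled analytically
    per grid SNR.
    """

    def __init__(
        self,
        s_l: np.ndarray,
        s_r: np.ndarray,
        n_l: np.ndarray,
        n_r: np.ndarray,
        sample_rate: float,
        ec_cfg: ECConfig,
        monaural_ear: str | None,
    ) -> None:
        self.fs = sample_rate
        self.monaural_ear = monaural_ear
        self.centers = band_center_frequencies()
        self.below = np.where(self.centers < ec_cfg.ec_cutoff_hz)[0]
        self.above = np.where(self.centers >= ec_cfg.ec_cutoff_hz)[0]
        n = s_l.shape[-1]
        self.n = n

        self.P_sL = np.mean(s_l**2, axis=-1)
        self.P_sR = np.mean(s_r**2, axis=-1)
        self.P_nL = np.mean(n_l**2, axis=-1)
        self.P_nR = np.mean(n_r**2, axis=-1)
        self.c_snL = np.mean(s_l * n_l, axis=-1)
        self.c_snR = np.mean(s_r * n_r, axis=-1)

        if monaural_ear is not None:
            return  # monaural bypass needs powers only

        F_sL = sfft.rfft(s_l, axis=-1)
        F_sR = sfft.rfft(s_r, axis=-1)
        F_nL = sfft.rfft(n_l, axis=-1)
        F_nR = sfft.rfft(n_r, axis=-1)
        nbins = F_sL.shape[-1]

        max_lag = min(int(round(ec_cfg.delay_search_range_s * sample_rate)), n // 2 - 1)
        lags = np.arange(-max_lag, max_lag + 1)
        self.lag0 = lags[0]

        def ccf_window(FL: np.ndarray, FR: np.ndarray) -> np.ndarray:
            full = sfft.irfft(np.conj(FL) * FR, n=n, axis=-1)
            return full[:, lags % n]

        bl = self.below
        self.c_ss = ccf_window(F_sL[bl], F_sR[bl])
        self.c_sn = ccf_window(F_sL[bl], F_nR[bl])
        self.c_ns = ccf_window(F_nL[bl], F_sR[bl])
        self.c_nn = ccf_window(F_nL[bl], F_nR[bl])

        # complex-baseband length (common to all bands)
        n2 = int(round(n * _BASEBAND_RATE_HZ / sample_rate))
        n2 += n2 % 2
        self.n2 = n2

        from .periphery import erb_bandwidth_hz

        # per-band support slice and absolute angular frequency (rad/sample)
        self.slices = []
        self.omega = []
        for i in range(self.centers.size):
            fc = self.centers[i]
            half_hz = min(4.0 * erb_bandwidth_hz(fc), 0.95 * _BASEBAND_RATE_HZ / 2.0)
            k0 = max(int((fc - half_hz) * n / sample_rate), 1)
            k1 = min(int((fc + half_hz) * n / sample_rate) + 2, nbins - 1)
            self.slices.append((k0, k1))
            self.omega.append(2.0 * np.pi * np.arange(k0, k1) / n)

        # banded cross-spectra for exact fractional-lag cross powers (EC bands)
        self.Z_ss = [np.conj(F_sL[i, k0:k1]) * F_sR[i, k0:k1] for i, (k0, k1) in self._bl_slices()]
        self.Z_nn = [np.conj(F_nL[i, k0:k1]) * F_nR[i, k0:k1] for i, (k0, k1) in self._bl_slices()]

        # baseband analytic signals (30, n2), scaled by n2/n like a decimation
        self.B_sL = self._baseband(F_sL)
        self.B_sR = self._baseband(F_sR)
        self.B_nL = self._baseband(F_nL)
        self.B_nR = self._baseband(F_nR)
        # sliced analytic spectra of the right ear for per-SNR fractional advance
        self.SA_sR = [2.0 * F_sR[i, k0:k1] for i, (k0, k1) in enumerate(self.slices)]
        self.SA_nR = [2.0 * F_nR[i, k0:k1] for i, (k0, k1) in enumerate(self.slices)]

    def _bl_slices(self):
        return [(i, self.slices[i]) for i in self.below]

    def _baseband(self, F: np.ndarray) -> np.ndarray:
        """Band-shifted decimated analytic signals, one row per band."""
        spec = np.zeros((F.shape[0], self.n2), dtype=np.complex64)
        for i, (k0, k1) in enumerate(self.slices):
            spec[i, : k1 - k0] = 2.0 * F[i, k0:k1]
        return sfft.ifft(spec, axis=-1, workers=1) * np.float32(self.n2 / self.n)

    def baseband_advanced_right(self, s: float, delays_s: np.ndarray) -> np.ndarray:
        """Baseband analytic right-ear mixture, each EC band advanced by its delay."""
        spec = np.zeros((self.below.size, self.n2), dtype=np.complex64)
        for pos, i in enumerate(self.below):
            k0, k1 = self.slices[i]
            ph = np.exp(1j * self.omega[i] * (delays_s[pos] * self.fs))
            spec[pos, : k1 - k0] = (s * self.SA_sR[i] + self.SA_nR[i]) * ph
        return sfft.ifft(spec, axis=-1, workers=1) * np.float32(self.n2 / self.n)

    def cross_power(self, which: str, band_pos: int, adv_samples: np.ndarray) -> np.ndarray:
        """mean(L[t] * R[t + d]) for a vector of advances d (in samples).

        Exact banded evaluation of the circular cross-correlation at a
        fractional lag: (2/N^2) * Re sum_k conj(F_L) F_R exp(+i w_k d).
        """
        Z = self.Z_ss[band_pos] if which == "speech" else self.Z_nn[band_pos]
        w = self.omega[self.below[band_pos]]
        ph = np.exp(1j * np.outer(np.atleast_1d(adv_samples), w))
        return (2.0 / self.n**2) * np.real(ph @ Z)


class SRTEngine:
    """Builds scenes, runs the model and solves SRTs, with caching.

    Scenes are keyed by the master seed so that, for a fixed seed, every
    listener is evaluated on identical external waveforms (only the TSN and
    spatial geometry differ); this keeps cross-listener and cross-method
    comparisons free of scene-sampling noise.
    """

    def __init__(
        self,
        solver: SolverConfig | None = None,
        ec: ECConfig | None = None,
        jitter: JitterConfig | None = None,
        srmr: SRMRConfig | None = None,
        sii_config: SIIConfig | None = None,
        tsn: TSNConfig | None = None,
        spatializer: sc.SpatializerConfig | None = None,
    ) -> None:
        self.solver = solver or SolverConfig()
        self.ec = ec or ECConfig(n_monte_carlo=(solver or SolverConfig()).n_monte_carlo)
        self.jitter = jitter or JitterConfig()
        self.srmr = srmr or SRMRConfig()
        self.sii_config = sii_config or SIIConfig()
        self.tsn = tsn or TSNConfig()
        self.spatializer = spatializer or sc.SpatializerConfig()
        self._curve_cache: dict = {}
        self._scene_cache: dict = {}
        self._tsn_cache: dict = {}

    # -- scene assembly ----------------------------------------------------

    def _speech_token(self, seed: int, t: int):
        key = ("speech", seed, t)
        if key not in self._scene_cache:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(1, t))
            tok = sc.make_speech_like_signal(
                self.solver.token_duration,
                seed=int(ss.generate_state(1)[0] % 2**31),
                sample_rate=self.solver.sample_rate,
                level_db_spl=self.solver.noise_level_db_spl,
            )
            self._scene_cache[key] = tok
        return self._scene_cache[key]

    def _noise_token(self, seed: int, t: int):
        key = ("noise", seed, t)
        if key not in self._scene_cache:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(2, t))
            ref = self._speech_token(seed, t)
            self._scene_cache[key] = sc.make_stationary_masker(
                ref,
                self.solver.token_duration,
                seed=int(ss.generate_state(1)[0] % 2**31),
                level_db_spl=self.solver.noise_level_db_spl,
            )
        return self._scene_cache[key]

    def _external_bands(self, seed: int, t: int, condition: str, worse_ear: str):
        """Gammatone bands of the spatialized unit-SNR speech and 65-dB noise."""
        key = ("bands", seed, t, condition, worse_ear)
        if key not in self._scene_cache:
            fs = self.solver.sample_rate
            speech = sc.spatialize(self._speech_token(seed, t), 0, self.spatializer)
            if condition == "S0N0":
                noise = sc.spatialize(self._noise_token(seed, t), 0, self.spatializer)
            else:
                azimuth = 90 if worse_ear == "right" else -90
                noise = sc.spatialize(self._noise_token(seed, t), azimuth, self.spatializer)
            arrs = {
                "s_l": gammatone_analyze_mono(speech.left.samples, fs),
                "s_r": gammatone_analyze_mono(speech.right.samples, fs),
                "n_l": gammatone_analyze_mono(noise.left.samples, fs),
                "n_r": gammatone_analyze_mono(noise.right.samples, fs),
            }
            self._scene_cache[key] = arrs
        return self._scene_cache[key]

    def _listener_key(self, listener: Listener) -> tuple:
        return (
            listener.id,
            listener.audiogram.left.tobytes(),
            listener.audiogram.right.tobytes(),
            listener.worse_ear,
        )

    def _tsn_bands(self, listener: Listener, seed: int):
        key = (self._listener_key(listener), seed)
        if key not in self._tsn_cache:
            fs = self.solver.sample_rate
            tsn = make_tsn(
                listener.audiogram,
                self.solver.token_duration,
                fs,
                self.tsn,
                seed=seed,
            )
            self._tsn_cache[key] = {
                "l": gammatone_analyze_mono(tsn.left.samples, fs),
                "r": gammatone_analyze_mono(tsn.right.samples, fs),
            }
        return self._tsn_cache[key]

    # -- the sweep ---------------------------------------------------------

    def sii_vs_snr(
        self,
        listener: Listener,
        condition: str,
        seed: int = 0,
        noise_increment_db: float = 0.0,
    ) -> PsychometricCurve:
        """Mean SII on the SNR grid for one listener and condition (cached)."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        key = (self._listener_key(listener), condition, seed, round(noise_increment_db, 9))
        if key not in self._curve_cache:
            self._curve_cache[key] = self._compute_curve(listener, condition, seed, noise_increment_db)
        return self._curve_cache[key]

    def _compute_curve(
        self,
        listener: Listener,
        condition: str,
        seed: int,
        noise_increment_db: float,
    ) -> PsychometricCurve:
        cfg = self.solver
        grid = cfg.snr_grid
        n_draws = cfg.n_monte_carlo
        draws = np.empty((grid.size, cfg.n_sentences * n_draws))
        flags: list = []
        cond_idx = CONDITIONS.index(condition)
        jit_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(4, cond_idx))
        )
        noise_gain = 10.0 ** (noise_increment_db / 20.0)
        monaural_ear = listener.better_ear if condition == "S0mN90m" else None

        for t in range(cfg.n_sentences):
            ext = self._external_bands(seed, t, condition, listener.worse_ear)
            tsn = self._tsn_bands(listener, seed)
            n_l = noise_gain * ext["n_l"] + tsn["l"]
            n_r = noise_gain * ext["n_r"] + tsn["r"]
            if monaural_ear is not None:
                # better ear only: gated channels are silent (TSN included)
                if monaural_ear == "left":
                    n_r = np.zeros_like(n_r)
                    s_l, s_r = ext["s_l"], np.zeros_like(ext["s_r"])
                else:
                    n_l = np.zeros_like(n_l)
                    s_l, s_r = np.zeros_like(ext["s_l"]), ext["s_r"]
            else:
                s_l, s_r = ext["s_l"], ext["s_r"]

            cache = _BandCache(s_l, s_r, n_l, n_r, cfg.sample_rate, self.ec, monaural_ear)
            block = self._sweep_token(cache, grid, n_draws, jit_rng)
            draws[:, t * n_draws : (t + 1) * n_draws] = block

        mean_sii = draws.mean(axis=1)
        return PsychometricCurve(snr_grid=grid, mean_sii=mean_sii, draws=draws, flags=flags)

    def _sweep_token(
        self,
        cache: _BandCache,
        grid: np.ndarray,
        n_draws: int,
        jit_rng: np.random.Generator,
    ) -> np.ndarray:
        """SII draws for one token over the grid -> (n_snr, n_draws)."""
        fs = cache.fs
        clamp = self.sii_config.snr_clamp_db
        weights = self.sii_config.band_importance
        n_bands = cache.centers.size
        out = np.empty((grid.size, n_draws))

        if cache.monaural_ear is not None:
            ear = cache.monaural_ear
            P_s = cache.P_sL if ear == "left" else cache.P_sR
            P_n = cache.P_nL if ear == "left" else cache.P_nR
            for gi, snr in enumerate(grid):
                s2 = 10.0 ** (snr / 10.0)
                with np.errstate(divide="ignore"):
                    snrs = 10.0 * np.log10(np.maximum(s2 * P_s, 1e-300) / np.maximum(P_n, 1e-300))
                snrs = np.clip(snrs, -clamp, clamp)
                out[gi, :] = sii(snrs, self.sii_config)
            return out

        bl, ab = cache.below, cache.above
        n, n2 = cache.n, cache.n2
        n_env = max(int(round(n * self.srmr.env_sample_rate / fs)), 16)
        env_fs = fs * n_env / n
        keep = min(int(np.ceil(self.srmr.env_lowpass_hz * n / fs)) + 1, n_env // 2 + 1)

        # jitter realizations: (n_snr, n_bl, n_draws)
        d_jit = jit_rng.normal(0.0, self.jitter.delay_jitter_sd_s, (grid.size, bl.size, n_draws)) \
            if self.jitter.delay_jitter_sd_s > 0 else np.zeros((grid.size, bl.size, n_draws))
        g_jit = jit_rng.normal(0.0, self.jitter.gain_jitter_sd_db, (grid.size, bl.size, n_draws)) \
            if self.jitter.gain_jitter_sd_db > 0 else np.zeros((grid.size, bl.size, n_draws))

        n_cand = 2 * ab.size + 2 * bl.size
        for gi, snr in enumerate(grid):
            s = 10.0 ** (snr / 20.0)
            s2 = s * s
            band_snr_db = np.empty((n_bands, n_draws))

            # ---- equalization per EC band (banded cross-correlation) ----
            delays = np.empty(bl.size)
            gains = np.empty(bl.size)
            for pos, i in enumerate(bl):
                cmix = s2 * cache.c_ss[pos] + s * (cache.c_sn[pos] + cache.c_ns[pos]) + cache.c_nn[pos]
                delays[pos] = (cache.lag0 + parabolic_argmax(cmix)) / fs
                P_l = s2 * cache.P_sL[i] + cache.P_nL[i] + 2.0 * s * cache.c_snL[i]
                P_r = s2 * cache.P_sR[i] + cache.P_nR[i] + 2.0 * s * cache.c_snR[i]
                gains[pos] = 10.0 * np.log10(max(P_r, 1e-300) / max(P_l, 1e-300))
            g_lin = 10.0 ** (-gains / 20.0)

            # ---- candidate envelopes (batched, complex baseband) ----
            A_r_adv = cache.baseband_advanced_right(s, delays)
            A_l_mix = s * cache.B_sL[bl] + cache.B_nL[bl]

            E = np.empty((n_cand, n2), dtype=np.float32)
            m_ab = ab.size
            E[0:2 * m_ab:2] = np.abs(s * cache.B_sL[ab] + cache.B_nL[ab])
            E[1:2 * m_ab:2] = np.abs(s * cache.B_sR[ab] + cache.B_nR[ab])
            gl = g_lin[:, None].astype(np.float32)
            E[2 * m_ab::2] = np.abs(A_l_mix - gl * A_r_adv) * 0.5
            E[2 * m_ab + 1::2] = np.abs(A_l_mix + gl * A_r_adv) * 0.5

            spec = sfft.rfft(E, axis=-1, workers=1)
            out_spec = np.zeros((n_cand, n_env // 2 + 1), dtype=np.complex64)
            out_spec[:, :keep] = spec[:, :keep]
            E_dec = sfft.irfft(out_spec, n=n_env, axis=-1, workers=1) * np.float32(n_env / n2)
            scores = _srmr_batch(E_dec.astype(np.float64), env_fs, self.srmr)

            # ---- assemble band SNRs ----
            for pos, i in enumerate(ab):
                ear = "right" if scores[2 * pos + 1] > scores[2 * pos] else "left"
                P_s = cache.P_sL[i] if ear == "left" else cache.P_sR[i]
                P_n = cache.P_nL[i] if ear == "left" else cache.P_nR[i]
                band_snr_db[i, :] = 10.0 * np.log10(max(s2 * P_s, 1e-300) / max(P_n, 1e-300))
            for pos, i in enumerate(bl):
                sc_min, sc_max = scores[2 * m_ab + 2 * pos], scores[2 * m_ab + 2 * pos + 1]
                sign = 1.0 if sc_max > sc_min else -1.0  # maximize: +, minimize: -
                d_j = (delays[pos] + d_jit[gi, pos]) * fs
                g_j = 10.0 ** (-(gains[pos] + g_jit[gi, pos]) / 20.0)
                cs = cache.cross_power("speech", pos, d_j)
                cn = cache.cross_power("noise", pos, d_j)
                P_speech = 0.25 * (cache.P_sL[i] + g_j**2 * cache.P_sR[i] + 2.0 * sign * g_j * cs) * s2
                P_noise = 0.25 * (cache.P_nL[i] + g_j**2 * cache.P_nR[i] + 2.0 * sign * g_j * cn)
                band_snr_db[i, :] = 10.0 * np.log10(
                    np.maximum(P_speech, 1e-300) / np.maximum(P_noise, 1e-300)
                )

            band_snr_db = np.clip(band_snr_db, -clamp, clamp)
            audibility = np.clip((band_snr_db + clamp) / (2.0 * clamp), 0.0, 1.0)
            out[gi, :] = weights @ audibility
        return out

    # -- prediction --------------------------------------------------------

    def predict_condition(
        self,
        listener: Listener,
        condition: str,
        method: str = "none",
        seed: int = 0,
    ) -> SRTResult:
        return [r for r in self.predict_all(listener, method, seed, conditions=(condition,))][0]

    def predict_all(
        self,
        listener: Listener,
        method: str = "none",
        seed: int = 0,
        conditions: tuple[str, ...] = CONDITIONS,
    ) -> list[SRTResult]:
        """SRTs for the requested conditions under one individualization method.

        For the ISC methods the S0N0 output is the calibration value (flagged
        ``fitted``), not a prediction.
        """
        if method not in ("none", "isc_sii", "isc_noise"):
            raise ValueError(f"unknown method {method!r}")
        results = []
        ref = self.solver.reference_sii
        increment = 0.0
        extra_flags: tuple = ()

        if method == "isc_sii":
            measured0 = self._require_measured(listener)
            curve0 = self.sii_vs_snr(listener, "S0N0", seed)
            ref, extra_flags = isc_sii_reference(curve0, measured0)
        elif method == "isc_noise":
            measured0 = self._require_measured(listener)
            curve0 = self.sii_vs_snr(listener, "S0N0", seed)
            pred0, _ = solve_srt(curve0, self.solver.reference_sii)
            increment = isc_noise_increment(measured0, pred0)

        for cond in conditions:
            curve = self.sii_vs_snr(listener, cond, seed, noise_increment_db=increment)
            srt, flags = solve_srt(curve, ref)
            all_flags = flags + extra_flags
            if method != "none" and cond == "S0N0":
                all_flags = all_flags + ("fitted",)
            results.append(
                SRTResult(
                    listener_id=listener.id,
                    condition=cond,
                    method=method,
                    srt_db=srt,
                    reference_sii_used=ref,
                    noise_increment_db=increment,
                    flags=all_flags,
                )
            )
        return results

    @staticmethod
    def _require_measured(listener: Listener) -> float:
        if "S0N0" not in listener.measured_srts:
            raise ValueError(
                f"listener {listener.id}: measured S0N0 SRT required for ISC methods"
            )
        return listener.measured_srts["S0N0"]
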