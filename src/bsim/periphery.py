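"""Auditory periphery: ERB-spaced gammatone filterbank and hearing-loss noise.

The filterbank uses 30 fourth-order gammatone filters with centre frequencies
equally spaced on the ERB-number scale from 146 Hz to about 8.3 kHz, covering
the speech-relevant range of the intelligibility index back-end.

Hearing loss is simulated with threshold-simulating noise (TSN): one
independent Gaussian noise per ear whose band spectrum level follows the
ear's audiogram, so that sub-threshold signal components are masked.  Because
the two ears' TSNs are drawn from independent streams they are interaurally
uncorrelated and cannot be removed by the equalization-cancellation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .cohort import AUDIOMETRIC_FREQS, Audiogram
from .scenes import BinauralScene, _silence_ear
from .signals import FULL_SCALE_DB_SPL, BinauralSignal, MonoSignal

N_BANDS = 30
F_LOW_HZ = 146.0
F_HIGH_HZ = 8300.0


# ---------------------------------------------------------------------------
# ERB scale (Glasberg & Moore parametrization)
# ---------------------------------------------------------------------------

def erb_bandwidth_hz(freq_hz):
    """Equivalent rectangular bandwidth of the auditory filter at ``freq_hz``."""
    f = np.asarray(freq_hz, dtype=float)
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


def erb_number(freq_hz):
    """ERB-number (Cam) corresponding to frequency in Hz."""
    f = np.asarray(freq_hz, dtype=float)
    return 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)


def erb_number_to_hz(erb):
    e = np.asarray(erb, dtype=float)
    return (10.0 ** (e / 21.4) - 1.0) / 4.37 * 1000.0


@lru_cache(maxsize=None)
def band_center_frequencies(n_bands: int = N_BANDS) -> np.ndarray:
    """Centre frequencies equally spaced in ERB number from F_LOW to F_HIGH."""
    lo, hi = erb_number(F_LOW_HZ), erb_number(F_HIGH_HZ)
    return erb_number_to_hz(np.linspace(lo, hi, n_bands))


def _gammatone_sos(fc: float, sample_rate: float) -> np.ndarray:
    """Fourth-order all-pole gammatone as 4 identical biquads, unit gain at fc.

    Pole radius follows the classical bandwidth parametrization
    b = 1.019 * ERB(fc); cascaded second-order sections keep the filtering
    numerically linear even at low fc / fs ratios.
    """
    T = 1.0 / sample_rate
    b = 1.019 * float(erb_bandwidth_hz(fc))
    r = np.exp(-2.0 * np.pi * b * T)
    theta = 2.0 * np.pi * fc * T
    section = np.array([1.0, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r])
    sos = np.tile(section, (4, 1))
    # normalize peak gain to 1 at fc
    _, h = sps.sosfreqz(sos, worN=[fc], fs=sample_rate)
    sos[:, :3] /= np.abs(h[0]) ** 0.25
    return sos


@lru_cache(maxsize=8)
def _filterbank(sample_rate: float) -> tuple:
    centers = band_center_frequencies()
    top_edge = centers[-1] + erb_bandwidth_hz(centers[-1])
    if sample_rate < 2.0 * top_edge:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for the {centers[-1]:.0f} Hz band"
        )
    return tuple(_gammatone_sos(fc, sample_rate) for fc in centers)


@dataclass
class BandSignals:
    """Per-band, per-ear time series from the gammatone analysis.

    ``left``/``right`` are (30, n_samples) arrays; a mono decomposition may
    leave ``right`` as None.
    """

    center_frequencies: np.ndarray
    left: np.ndarray
    right: np.ndarray | None
    sample_rate: float

    @property
    def n_bands(self) -> int:
        return self.center_frequencies.size

    def ear(self, which: str) -> np.ndarray:
        if which == "left":
            return self.left
        if which == "right":
            if self.right is None:
                raise ValueError("no right-ear bands present")
            return self.right
        raise ValueError(f"unknown ear {which!r}")


def gammatone_analyze_mono(samples: np.ndarray, sample_rate: float) -> np.ndarray:
    """Decompose one waveform into the 30 gammatone bands -> (30, N) array."""
    bank = _filterbank(float(sample_rate))
    out = np.empty((len(bank), samples.size))
    for i, sos in enumerate(bank):
        out[i] = sps.sosfilt(sos, samples)
    return out


def gammatone_analyze(signal: BinauralSignal) -> BandSignals:
    """Gammatone decomposition of both ears of a binaural signal."""
    fs = signal.sample_rate
    return BandSignals(
        center_frequencies=band_center_frequencies(),
        left=gammatone_analyze_mono(signal.left.samples, fs),
        right=gammatone_analyze_mono(signal.right.samples, fs),
        sample_rate=fs,
    )


# ---------------------------------------------------------------------------
# threshold-simulating noise
# ---------------------------------------------------------------------------

#: monaural pure-tone threshold reference (dB SPL at 0 dB HL), free-field-like
#: values at the audiometric frequencies; declared package constants.
REFERENCE_THRESHOLD_DB_SPL = np.array([11.4, 4.4, 2.4, -1.3, -5.8, -5.4, 4.3])


@dataclass
class TSNConfig:
    """Calibration of the threshold-simulating noise.

    The band spectrum level at frequency f is

        HL(f) + T_ref(f) - 10*log10(ERB(f)) + offset_db

    with HL interpolated linearly in log-frequency between audiometric points
    (held constant beyond the ends).  With ``offset_db = 0`` a pure tone at
    threshold yields roughly 0 dB SNR within its auditory band.
    """

    reference_thresholds_db_spl: np.ndarray = field(
        default_factory=lambda: REFERENCE_THRESHOLD_DB_SPL.copy()
    )
    offset_db: float = 0.0

    def spectrum_level_db_spl(self, freq_hz: np.ndarray, thresholds_db_hl: np.ndarray) -> np.ndarray:
        f = np.maximum(np.asarray(freq_hz, dtype=float), 1.0)
        logf = np.log10(f)
        log_aud = np.log10(AUDIOMETRIC_FREQS)
        hl = np.interp(logf, log_aud, thresholds_db_hl)
        ref = np.interp(logf, log_aud, self.reference_thresholds_db_spl)
        return hl + ref - 10.0 * np.log10(erb_bandwidth_hz(f)) + self.offset_db


def _tsn_mono(
    thresholds_db_hl: np.ndarray,
    duration: float,
    sample_rate: float,
    config: TSNConfig,
    rng: np.random.Generator,
) -> MonoSignal:
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    lvl = config.spectrum_level_db_spl(freqs, thresholds_db_hl)
    # spectrum level (dB SPL per Hz) -> one-sided PSD on the package calibration
    psd = 10.0 ** ((lvl - FULL_SCALE_DB_SPL) / 10.0)
    df = sample_rate / n
    amp = np.sqrt(psd * df * n**2 / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    return MonoSignal(np.fft.irfft(spec, n=n), sample_rate)


def make_tsn(
    audiogram: Audiogram,
    duration: float,
    sample_rate: float,
    config: TSNConfig | None = None,
    seed: int = 0,
) -> BinauralSignal:
    """Interaurally uncorrelated threshold-simulating noise pair for one listener."""
    config = config or TSNConfig()
    rng_l = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    rng_r = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(102,)))
    return BinauralSignal(
        left=_tsn_mono(audiogram.left, duration, sample_rate, config, rng_l),
        right=_tsn_mono(audiogram.right, duration, sample_rate, config, rng_r),
    )


def add_tsn(scene: BinauralScene, tsn: BinauralSignal) -> BinauralScene:
    """Add the TSN to the scene's noise path (speech is untouched).

    The TSN acts as an additional masker component, so it must degrade the
    band SNR exactly as an external noise would; in the monaural condition the
    gated ear stays silent.
    """
    if tsn.n_samples != scene.noise.n_samples or tsn.sample_rate != scene.sample_rate:
        raise ValueError("TSN length/sample rate must match the scene")
    if scene.condition == "S0mN90m":
        tsn = _silence_ear(tsn, scene.worse_ear)
    return BinauralScene(
        speech=scene.speech,
        noise=scene.noise.plus(tsn),
        condition=scene.condition,
        worse_ear=scene.worse_ear,
        snr_db=scene.snr_db,
        noise_level_db_spl=scene.noise_level_db_spl,
        config=scene.config,
    )
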