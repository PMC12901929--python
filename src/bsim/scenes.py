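"""Synthetic binaural speech-in-noise scenes.

Generates the three spatial conditions used throughout the package without any
external audio: a speech-like target (speech-shaped noise carrying a slow,
roughly 4-Hz envelope modulation), a stationary masker spectrally matched to
the target's long-term spectrum, and a parametric ITD+ILD spatializer standing
in for measured head-related transfer functions.

Conditions
----------
``S0N0``     speech and noise both frontal (diotic).
``S0N90``    speech frontal, noise at +/-90 degrees toward the worse ear.
``S0mN90m``  as ``S0N90`` but presented monaurally to the better ear
             (the worse-ear channel is silenced).

The SNR convention is free-field: ``snr_db`` relates the broadband levels of
the pre-spatialization speech and noise; per-ear SNRs in the spatial
conditions emerge from the ITD/ILD cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .signals import BinauralSignal, MonoSignal, db_spl_to_rms

CONDITIONS = ("S0N0", "S0N90", "S0mN90m")

DEFAULT_SAMPLE_RATE = 44100.0
#: duration of one synthetic "sentence" token in seconds
DEFAULT_TOKEN_DURATION = 2.0
#: number of sentence tokens per SRT prediction
DEFAULT_N_TOKENS = 10
DEFAULT_NOISE_LEVEL_DB_SPL = 65.0


# ---------------------------------------------------------------------------
# spectral shaping helpers
# ---------------------------------------------------------------------------

def speech_spectrum_level_db(freq_hz: np.ndarray) -> np.ndarray:
    """Long-term speech-shaped spectrum template (relative dB).

    Flat between 100 and 500 Hz, falling at 9 dB/octave above 500 Hz and
    rising at 24 dB/octave below 100 Hz (steep low cut), which concentrates
    the energy in the 100-6000 Hz region like a long-term average speech
    spectrum.
    """
    f = np.maximum(np.asarray(freq_hz, dtype=float), 1e-3)
    lvl = np.zeros_like(f)
    hi = f > 500.0
    lvl[hi] = -9.0 * np.log2(f[hi] / 500.0)
    lo = f < 100.0
    lvl[lo] = -24.0 * np.log2(100.0 / f[lo])
    return lvl


def _shape_noise(n: int, sample_rate: float, level_db: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian noise spectrally shaped to ``level_db`` (relative dB)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x) * 10.0 ** (level_db / 20.0)
    return np.fft.irfft(spec, n=n)


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

def make_speech_like_signal(
    duration: float,
    seed: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    level_db_spl: float = DEFAULT_NOISE_LEVEL_DB_SPL,
    modulation_depth: float = 0.6,
) -> MonoSignal:
    """Speech-shaped noise with a slow (about 4 Hz) envelope modulation.

    The carrier is Gaussian noise shaped to the speech spectrum template; the
    envelope is ``1 + m(t)`` with ``m`` a 2-8 Hz band-limited Gaussian
    modulator scaled to ``modulation_depth`` (clipped at zero), so the
    modulation spectrum peaks in the syllabic 2-8 Hz range.
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s to define a long-term spectrum")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    carrier = _shape_noise(n, sample_rate, speech_spectrum_level_db(freqs), rng)

    mod = rng.standard_normal(n)
    sos = sps.butter(2, [2.0, 8.0], btype="bandpass", fs=sample_rate, output="sos")
    mod = sps.sosfiltfilt(sos, mod)
    mod = mod / max(np.std(mod), 1e-12) * modulation_depth
    envelope = np.maximum(1.0 + mod, 0.0)

    out = MonoSignal(carrier * envelope, sample_rate)
    return out.scaled_to(level_db_spl)


def make_stationary_masker(
    reference: MonoSignal,
    duration: float,
    seed: int,
    level_db_spl: float = DEFAULT_NOISE_LEVEL_DB_SPL,
) -> MonoSignal:
    """Stationary Gaussian noise spectrally matched to ``reference``.

    The reference's long-term spectrum is estimated with Welch's method and
    imposed on a fresh white-noise draw, yielding an unmodulated masker whose
    octave-band levels track the reference.
    """
    if reference.duration < 1.0:
        raise ValueError("reference must be at least 1 s long for spectral estimation")
    fs = reference.sample_rate
    nperseg = int(fs * 0.1)
    f_w, psd = sps.welch(reference.samples, fs=fs, nperseg=nperseg)
    psd = np.maximum(psd, psd.max() * 1e-12)

    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    level_db = np.interp(freqs, f_w, 10.0 * np.log10(psd))
    rng = np.random.default_rng(seed)
    out = MonoSignal(_shape_noise(n, fs, level_db, rng), fs)
    return out.scaled_to(level_db_spl)


# ---------------------------------------------------------------------------
# spatialization
# ---------------------------------------------------------------------------

@dataclass
class SpatializerConfig:
    """Parametric ITD+ILD head model for lateral sources at +/-90 degrees.

    ``itd_at_90deg`` delays the contralateral ear; the ILD profile attenuates
    it by 0 dB below ``ild_lo_hz`` rising linearly in log-frequency to
    ``ild_max_db`` at ``ild_hi_hz`` and above -- values typical for a human
    head, not calibrated to any measured HRTF set.
    """

    itd_at_90deg: float = 700e-6
    ild_max_db: float = 10.0
    ild_lo_hz: float = 500.0
    ild_hi_hz: float = 4000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.itd_at_90deg <= 1e-3:
            raise ValueError("itd_at_90deg must lie in [0, 1 ms]")
        if self.ild_max_db < 0.0:
            raise ValueError("ILD attenuation must be non-negative")

    def ild_db(self, freq_hz: np.ndarray) -> np.ndarray:
        """Head-shadow attenuation in dB at the contralateral ear."""
        f = np.maximum(np.asarray(freq_hz, dtype=float), 1e-3)
        t = np.log(f / self.ild_lo_hz) / np.log(self.ild_hi_hz / self.ild_lo_hz)
        return self.ild_max_db * np.clip(t, 0.0, 1.0)


def _delay_and_shadow(signal: MonoSignal, config: SpatializerConfig) -> MonoSignal:
    """Contralateral-ear path: fractional ITD delay plus ILD attenuation."""
    n = signal.n_samples
    spec = np.fft.rfft(signal.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / signal.sample_rate)
    spec *= np.exp(-2j * np.pi * freqs * config.itd_at_90deg)
    spec *= 10.0 ** (-config.ild_db(freqs) / 20.0)
    return MonoSignal(np.fft.irfft(spec, n=n), signal.sample_rate)


def spatialize(signal: MonoSignal, azimuth: float, config: SpatializerConfig | None = None) -> BinauralSignal:
    """Place a mono source at 0, +90 (right) or -90 (left) degrees azimuth."""
    config = config or SpatializerConfig()
    if azimuth == 0:
        return BinauralSignal.diotic(signal)
    if azimuth == 90:
        ipsi, contra = signal, _delay_and_shadow(signal, config)
        return BinauralSignal(left=contra, right=MonoSignal(ipsi.samples.copy(), ipsi.sample_rate))
    if azimuth == -90:
        ipsi, contra = signal, _delay_and_shadow(signal, config)
        return BinauralSignal(left=MonoSignal(ipsi.samples.copy(), ipsi.sample_rate), right=contra)
    raise ValueError("azimuth must be one of 0, +90, -90 degrees")


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class BinauralScene:
    """Calibrated binaural speech and noise pair for one spatial condition."""

    speech: BinauralSignal
    noise: BinauralSignal
    condition: str
    worse_ear: str
    snr_db: float
    noise_level_db_spl: float = DEFAULT_NOISE_LEVEL_DB_SPL
    config: SpatializerConfig = field(default_factory=SpatializerConfig)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.worse_ear not in ("left", "right"):
            raise ValueError("worse_ear must be 'left' or 'right'")
        if self.speech.sample_rate != self.noise.sample_rate:
            raise ValueError("speech and noise sample rates differ")
        if self.speech.n_samples != self.noise.n_samples:
            raise ValueError("speech and noise lengths differ")

    @property
    def better_ear(self) -> str:
        return "right" if self.worse_ear == "left" else "left"

    @property
    def sample_rate(self) -> float:
        return self.speech.sample_rate

    def mixture(self) -> BinauralSignal:
        return self.speech.plus(self.noise)


def build_scene(
    speech: MonoSignal,
    noise: MonoSignal,
    condition: str,
    worse_ear: str,
    snr_db: float,
    noise_level_db_spl: float = DEFAULT_NOISE_LEVEL_DB_SPL,
    config: SpatializerConfig | None = None,
) -> BinauralScene:
    """Assemble a scene: speech at 0 deg, noise per condition, calibrated levels.

    The mono sources are first scaled (noise to ``noise_level_db_spl``, speech
    to ``noise_level_db_spl + snr_db``), then spatialized. In ``S0mN90m`` the
    worse-ear channel of both sources is silenced ("better ear only").
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    if speech.sample_rate != noise.sample_rate:
        raise ValueError("speech and noise sample rates differ")
    config = config or SpatializerConfig()

    speech_cal = speech.scaled_to(noise_level_db_spl + snr_db)
    noise_cal = noise.scaled_to(noise_level_db_spl)

    speech_bin = spatialize(speech_cal, 0, config)
    if condition == "S0N0":
        noise_bin = spatialize(noise_cal, 0, config)
    else:
        azimuth = 90 if worse_ear == "right" else -90
        noise_bin = spatialize(noise_cal, azimuth, config)

    if condition == "S0mN90m":
        speech_bin = _silence_ear(speech_bin, worse_ear)
        noise_bin = _silence_ear(noise_bin, worse_ear)

    return BinauralScene(
        speech=speech_bin,
        noise=noise_bin,
        condition=condition,
        worse_ear=worse_ear,
        snr_db=snr_db,
        noise_level_db_spl=noise_level_db_spl,
        config=config,
    )


def _silence_ear(signal: BinauralSignal, ear: str) -> BinauralSignal:
    zero = MonoSignal(np.zeros(signal.n_samples), signal.sample_rate)
    if ear == "left":
        return BinauralSignal(left=zero, right=signal.right)
    return BinauralSignal(left=signal.left, right=zero)


# ---------------------------------------------------------------------------
# WAV + sidecar I/O
# ---------------------------------------------------------------------------

def save_scene(scene: BinauralScene, prefix: str | Path) -> None:
    """Write ``<prefix>_speech.wav``, ``<prefix>_noise.wav`` and a metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fs = int(scene.sample_rate)
    for name, pair in (("speech", scene.speech), ("noise", scene.noise)):
        data = np.stack([pair.left.samples, pair.right.samples], axis=1).astype(np.float32)
        wavfile.write(f"{prefix}_{name}.wav", fs, data)
    meta = {
        "condition": scene.condition,
        "worse_ear": scene.worse_ear,
        "snr_db": f"{scene.snr_db:.6f}",
        "noise_level_db_spl": f"{scene.noise_level_db_spl:.6f}",
        "sample_rate": f"{fs}",
    }
    Path(f"{prefix}_meta.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in meta.items()), encoding="utf-8"
    )


def load_scene(prefix: str | Path) -> BinauralScene:
    """Read a scene written by :func:`save_scene`."""
    prefix = Path(prefix)
    meta: dict[str, str] = {}
    for line in Path(f"{prefix}_meta.txt").read_text(encoding="utf-8").splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    pairs = {}
    for name in ("speech", "noise"):
        fs, data = wavfile.read(f"{prefix}_{name}.wav")
        data = np.asarray(data, dtype=np.float64)
        pairs[name] = BinauralSignal(
            MonoSignal(data[:, 0], float(fs)), MonoSignal(data[:, 1], float(fs))
        )
    return BinauralScene(
        speech=pairs["speech"],
        noise=pairs["noise"],
        condition=meta["condition"],
        worse_ear=meta["worse_ear"],
        snr_db=float(meta["snr_db"]),
        noise_level_db_spl=float(meta["noise_level_db_spl"]),
    )
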