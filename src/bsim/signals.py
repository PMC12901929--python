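"""Calibrated mono and binaural pressure signals.

All waveforms in this package live on a common digital calibration: an RMS
amplitude of 1.0 corresponds to ``FULL_SCALE_DB_SPL`` dB SPL.  Levels are
therefore properties of the samples, never stored separately, which keeps the
"RMS consistent with level" invariant true by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: dB SPL carried by a waveform with RMS amplitude 1.0.
FULL_SCALE_DB_SPL = 100.0

#: Smallest RMS treated as non-silent when computing levels.
_SILENCE_RMS = 1e-12


def db_spl_to_rms(level_db_spl: float) -> float:
    """RMS amplitude corresponding to a broadband level in dB SPL."""
    return 10.0 ** ((level_db_spl - FULL_SCALE_DB_SPL) / 20.0)


def rms_to_db_spl(rms: float) -> float:
    """Broadband level in dB SPL for an RMS amplitude (``-inf`` for silence)."""
    if rms < _SILENCE_RMS:
        return -np.inf
    return FULL_SCALE_DB_SPL + 20.0 * np.log10(rms)


@dataclass
class MonoSignal:
    """A single calibrated pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Finite float waveform on the package calibration.
    sample_rate : float
        Sampling rate in Hz; must exceed 8 kHz so the auditory filterbank
        can resolve its highest band.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("MonoSignal samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("MonoSignal samples must be finite")
        if self.sample_rate <= 8000.0:
            raise ValueError("sample_rate must exceed 8000 Hz")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def level_db_spl(self) -> float:
        """Broadband level implied by the calibration (-inf for silence)."""
        return rms_to_db_spl(self.rms)

    def scaled_to(self, level_db_spl: float) -> "MonoSignal":
        """Return a copy rescaled to the requested broadband level."""
        rms = self.rms
        if rms < _SILENCE_RMS:
            raise ValueError("cannot rescale a silent signal to a finite level")
        gain = db_spl_to_rms(level_db_spl) / rms
        return MonoSignal(self.samples * gain, self.sample_rate)

    def scaled_by(self, gain_db: float) -> "MonoSignal":
        return MonoSignal(self.samples * 10.0 ** (gain_db / 20.0), self.sample_rate)


@dataclass
class BinauralSignal:
    """Left/right pair of calibrated waveforms with matching geometry."""

    left: MonoSignal
    right: MonoSignal

    def __post_init__(self) -> None:
        if self.left.n_samples != self.right.n_samples:
            raise ValueError("left and right channels must have equal length")
        if self.left.sample_rate != self.right.sample_rate:
            raise ValueError("left and right channels must share a sample rate")

    @property
    def sample_rate(self) -> float:
        return self.left.sample_rate

    @property
    def n_samples(self) -> int:
        return self.left.n_samples

    def channel(self, ear: str) -> MonoSignal:
        if ear == "left":
            return self.left
        if ear == "right":
            return self.right
        raise ValueError(f"unknown ear {ear!r}")

    def scaled_by(self, gain_db: float) -> "BinauralSignal":
        return BinauralSignal(self.left.scaled_by(gain_db), self.right.scaled_by(gain_db))

    def plus(self, other: "BinauralSignal") -> "BinauralSignal":
        if other.n_samples != self.n_samples or other.sample_rate != self.sample_rate:
            raise ValueError("signals must match in length and sample rate")
        return BinauralSignal(
            MonoSignal(self.left.samples + other.left.samples, self.sample_rate),
            MonoSignal(self.right.samples + other.right.samples, self.sample_rate),
        )

    @staticmethod
    def diotic(signal: MonoSignal) -> "BinauralSignal":
        return BinauralSignal(
            MonoSignal(signal.samples.copy(), signal.sample_rate),
            MonoSignal(signal.samples.copy(), signal.sample_rate),
        )
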