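"""Speech intelligibility index back-end on the 30 gammatone bands.

A stripped-down band-audibility SII: per-band SNRs from shadow-filtered
speech and noise, clamped to +/-15 dB, mapped linearly to [0, 1] via
(SNR+15)/30, weighted by the critical-band importance function interpolated
to the gammatone centres, and summed.  Hearing loss is deliberately *not*
part of this stage -- it is carried entirely by the threshold-simulating
noise added in the front-end -- and the level-distortion and
spread-of-masking terms of the full standard procedure are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ec import ECParameters, apply_disposition
from .periphery import BandSignals, band_center_frequencies, erb_number

SNR_CLAMP_DB = 15.0

#: critical-band importance function of the ANSI band-audibility procedure:
#: 21 critical-band centre frequencies and their importances (sum = 1).
_CB_FREQS = np.array([
    150.0, 250.0, 350.0, 450.0, 570.0, 700.0, 840.0, 1000.0, 1170.0, 1370.0,
    1600.0, 1850.0, 2150.0, 2500.0, 2900.0, 3400.0, 4000.0, 4800.0, 5800.0,
    7000.0, 8500.0,
])
_CB_IMPORTANCE = np.array([
    0.0103, 0.0261, 0.0419, 0.0577, 0.0577, 0.0577, 0.0577, 0.0577, 0.0577,
    0.0577, 0.0577, 0.0577, 0.0577, 0.0577, 0.0577, 0.0577, 0.0577, 0.0460,
    0.0343, 0.0226, 0.0110,
])


def band_importance(center_frequencies: np.ndarray | None = None) -> np.ndarray:
    """Importance weights at the gammatone centres (interpolated in ERB number,
    renormalized to sum 1)."""
    centers = center_frequencies if center_frequencies is not None else band_center_frequencies()
    w = np.interp(erb_number(centers), erb_number(_CB_FREQS), _CB_IMPORTANCE)
    return w / w.sum()


def dump_band_importance(path, center_frequencies: np.ndarray | None = None) -> None:
    """Write the per-band importance weights to a TSV for inspection."""
    centers = center_frequencies if center_frequencies is not None else band_center_frequencies()
    w = band_importance(centers)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("center_hz\timportance\n")
        for fc, wi in zip(centers, w):
            fh.write(f"{fc:.1f}\t{wi:.6f}\n")


@dataclass
class SIIConfig:
    band_importance: np.ndarray = field(default_factory=band_importance)
    snr_clamp_db: float = SNR_CLAMP_DB

    def __post_init__(self) -> None:
        w = np.asarray(self.band_importance, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("band importance weights must be >= 0 and sum to 1")
        self.band_importance = w


def shadow_filter(
    speech_bands: BandSignals,
    noise_bands: BandSignals,
    params: ECParameters,
    draw: int | None = None,
) -> tuple[BandSignals, BandSignals]:
    """Apply the frozen front-end dispositions to speech and noise separately.

    Because every disposition is linear, the sum of the two outputs equals
    the processed mixture exactly ("ideal shadow filtering"), which is what
    lets the non-blind index see clean per-band SNRs.
    """
    if len(params.bands) != speech_bands.n_bands or len(params.bands) != noise_bands.n_bands:
        raise ValueError("parameter/band count mismatch")
    return (
        apply_disposition(speech_bands, params, draw=draw),
        apply_disposition(noise_bands, params, draw=draw),
    )


def band_snr(
    speech_bands: BandSignals | np.ndarray,
    noise_bands: BandSignals | np.ndarray,
    clamp_db: float = SNR_CLAMP_DB,
) -> np.ndarray:
    """Per-band SNR in dB, clamped to +/-``clamp_db``.

    Accepts processed (mono) band signals or plain (n_bands, n) arrays; a
    band with zero noise power clamps to the upper bound.
    """
    s = speech_bands.left if isinstance(speech_bands, BandSignals) else np.asarray(speech_bands)
    n = noise_bands.left if isinstance(noise_bands, BandSignals) else np.asarray(noise_bands)
    ps = np.mean(s**2, axis=-1)
    pn = np.mean(n**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 10.0 * np.log10(ps / pn)
    snr = np.where(pn <= 0.0, clamp_db, snr)
    snr = np.where(ps <= 0.0, -clamp_db, snr)
    return np.clip(snr, -clamp_db, clamp_db)


def sii(snr_db: np.ndarray, config: SIIConfig | None = None) -> float:
    """Weighted sum of normalized band SNRs: sum_i w_i * clip((SNR_i+15)/30, 0, 1)."""
    config = config or SIIConfig()
    snr_db = np.asarray(snr_db, dtype=float)
    if snr_db.shape[-1] != config.band_importance.size:
        raise ValueError("band count does not match the importance weights")
    c = config.snr_clamp_db
    audibility = np.clip((snr_db + c) / (2.0 * c), 0.0, 1.0)
    return float(np.dot(audibility, config.band_importance))
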