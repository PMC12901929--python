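"""Synthetic listener cohorts: audiograms, groups, suprathreshold offsets.

Audiogram templates follow the qualitative shape taxonomy of the Bisgaard
classification -- flat-to-gently-sloping losses of increasing severity
(N1..N4) and steeply sloping high-frequency losses (S1..S3) -- plus a
normal-hearing (NH) template.  The template values are package constants
chosen to respect the taxonomy's shape/severity ordering; they are stand-ins,
not calibrated group means.

Each listener additionally carries a ground-truth individual suprathreshold
offset (``isc_offset_db``): an additive, condition-independent dB shift of the
"measured" SRTs relative to what audibility alone predicts.  This is the
simplest structure both individualization schemes downstream should recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AUDIOMETRIC_FREQS = np.array([250.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0, 6000.0])

GROUPS = ("NH", "N1", "N2", "N3", "N4", "S1", "S2", "S3")

#: dB HL at AUDIOMETRIC_FREQS; severity strictly increases N1 < N2 < N3 < N4,
#: S groups are near-normal at 250 Hz and steep toward 6 kHz (>= 30 dB span).
GROUP_TEMPLATES: dict[str, np.ndarray] = {
    "NH": np.array([5.0, 5.0, 5.0, 10.0, 10.0, 10.0, 15.0]),
    "N1": np.array([10.0, 10.0, 10.0, 15.0, 20.0, 25.0, 30.0]),
    "N2": np.array([20.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0]),
    "N3": np.array([35.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0]),
    "N4": np.array([55.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0]),
    "S1": np.array([10.0, 10.0, 15.0, 30.0, 45.0, 55.0, 60.0]),
    "S2": np.array([20.0, 20.0, 30.0, 50.0, 65.0, 75.0, 80.0]),
    "S3": np.array([35.0, 40.0, 55.0, 75.0, 85.0, 90.0, 95.0]),
}

#: group means of the suprathreshold offset in dB (positive for impaired groups)
GROUP_ISC_MEAN_DB: dict[str, float] = {
    "NH": 0.0, "N1": 1.0, "N2": 2.0, "N3": 3.0, "N4": 4.0,
    "S1": 2.0, "S2": 3.0, "S3": 4.0,
}

HL_MIN, HL_MAX = -10.0, 120.0
#: frequencies entering the pure-tone average (PTA4)
_PTA_FREQS = (500.0, 1000.0, 2000.0, 4000.0)


@dataclass
class Audiogram:
    """Per-ear hearing thresholds in dB HL at the fixed audiometric frequencies."""

    left: np.ndarray
    right: np.ndarray
    frequencies: np.ndarray = field(default_factory=lambda: AUDIOMETRIC_FREQS.copy())

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not np.array_equal(self.frequencies, AUDIOMETRIC_FREQS):
            raise ValueError("audiogram must use the fixed audiometric frequency set")
        for ear in (self.left, self.right):
            if ear.shape != AUDIOMETRIC_FREQS.shape:
                raise ValueError("one threshold per audiometric frequency is required")
            if np.any(ear < HL_MIN) or np.any(ear > HL_MAX):
                raise ValueError(f"thresholds must lie in [{HL_MIN}, {HL_MAX}] dB HL")

    def ear(self, which: str) -> np.ndarray:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError(f"unknown ear {which!r}")

    def pta(self, which: str) -> float:
        """Four-frequency pure-tone average (0.5/1/2/4 kHz) in dB HL."""
        idx = [int(np.where(AUDIOMETRIC_FREQS == f)[0][0]) for f in _PTA_FREQS]
        return float(np.mean(self.ear(which)[idx]))

    @property
    def worse_ear(self) -> str:
        return "left" if self.pta("left") >= self.pta("right") else "right"


@dataclass
class Listener:
    id: str
    audiogram: Audiogram
    group: str
    worse_ear: str
    isc_offset_db: float = 0.0
    measured_srts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.worse_ear not in ("left", "right"):
            raise ValueError("worse_ear must be 'left' or 'right'")

    @property
    def better_ear(self) -> str:
        return "right" if self.worse_ear == "left" else "left"


def group_template_audiogram(group: str, jitter_db: float = 0.0, seed: int = 0) -> Audiogram:
    """Symmetric audiogram drawn around a group template with Gaussian jitter."""
    if group not in GROUP_TEMPLATES:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    base = GROUP_TEMPLATES[group]
    left = np.clip(base + rng.normal(0.0, jitter_db, base.size) if jitter_db > 0 else base.copy(), HL_MIN, HL_MAX)
    right = np.clip(base + rng.normal(0.0, jitter_db, base.size) if jitter_db > 0 else base.copy(), HL_MIN, HL_MAX)
    return Audiogram(left=left, right=right)


def synthesize_cohort(
    n: int,
    group_mix: dict[str, float] | None = None,
    asym_fraction: float = 0.0,
    isc_sd_db: float = 3.0,
    jitter_db: float = 3.0,
    seed: int = 0,
) -> list[Listener]:
    """Draw ``n`` listeners with group labels, audiograms and ISC offsets.

    ``asym_fraction`` of the cohort get an interaural asymmetry: one ear is
    shifted upward by 20-60 dB (clipped to the audiogram range).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    group_mix = group_mix or {g: 1.0 / len(GROUPS) for g in GROUPS}
    probs = np.array([group_mix.get(g, 0.0) for g in GROUPS], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("group_mix proportions must sum to 1")

    rng = np.random.default_rng(seed)
    listeners: list[Listener] = []
    for i in range(n):
        group = str(rng.choice(GROUPS, p=probs))
        audio = group_template_audiogram(group, jitter_db=jitter_db, seed=int(rng.integers(2**31)))
        left, right = audio.left.copy(), audio.right.copy()
        if rng.random() < asym_fraction:
            shift = rng.uniform(20.0, 60.0)
            if rng.random() < 0.5:
                left = np.clip(left + shift, HL_MIN, HL_MAX)
            else:
                right = np.clip(right + shift, HL_MIN, HL_MAX)
        else:
            # break exact PTA ties so the worse ear is well defined
            if np.isclose(Audiogram(left, right).pta("left"), Audiogram(left, right).pta("right")):
                bump = 0.5 if rng.random() < 0.5 else -0.5
                left = np.clip(left + bump, HL_MIN, HL_MAX)
        audio = Audiogram(left=left, right=right)
        isc = GROUP_ISC_MEAN_DB[group] + (rng.normal(0.0, isc_sd_db) if isc_sd_db > 0 else 0.0)
        listeners.append(
            Listener(
                id=f"L{i:04d}",
                audiogram=audio,
                group=group,
                worse_ear=audio.worse_ear,
                isc_offset_db=float(isc),
            )
        )
    return listeners


def simulate_measured_srts(
    listener: Listener,
    engine,
    measurement_noise_sd_db: float = 1.0,
    seed: int = 0,
    conditions: tuple[str, ...] = ("S0N0", "S0N90", "S0mN90m"),
    noise_seed: int | None = None,
) -> dict[str, float]:
    """Synthesize "measured" SRTs from model predictions plus the ISC ground truth.

    measured(c) = predicted_no_isc(c) + isc_offset_db + N(0, noise_sd); the
    same offset is applied to every condition (the suprathreshold deficit is
    modelled as condition-independent, so it cancels in SRM/BRM/BEL).
    ``seed`` drives the model scenes (shared across listeners);
    ``noise_seed`` (default: derived from seed and listener id) drives the
    per-listener measurement noise.
    """
    if noise_seed is None:
        noise_seed = zlib.crc32(f"{listener.id}:{seed}".encode()) % 2**31
    rng = np.random.default_rng(noise_seed)
    measured = {}
    for cond in conditions:
        res = engine.predict_condition(listener, cond, method="none", seed=seed)
        noise = rng.normal(0.0, measurement_noise_sd_db) if measurement_noise_sd_db > 0 else 0.0
        measured[cond] = float(res.srt_db + listener.isc_offset_db + noise)
    listener.measured_srts.update(measured)
    return measured


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_AUDIOGRAM_COLS = ["id", "ear"] + [f"f{int(f)}" for f in AUDIOMETRIC_FREQS]


def write_audiograms_csv(listeners: list[Listener], path: str | Path) -> None:
    rows = []
    for lst in listeners:
        for ear in ("left", "right"):
            rows.append([lst.id, ear] + list(lst.audiogram.ear(ear)))
    pd.DataFrame(rows, columns=_AUDIOGRAM_COLS).to_csv(path, index=False)


def read_audiograms_csv(path: str | Path) -> dict[str, Audiogram]:
    df = pd.read_csv(path)
    out: dict[str, Audiogram] = {}
    for lid, sub in df.groupby("id", sort=False):
        ears = {}
        for _, row in sub.iterrows():
            ears[row["ear"]] = np.array([row[f"f{int(f)}"] for f in AUDIOMETRIC_FREQS], dtype=float)
        if set(ears) != {"left", "right"}:
            raise ValueError(f"listener {lid}: need exactly one row per ear")
        out[str(lid)] = Audiogram(left=ears["left"], right=ears["right"])
    return out


def write_measured_tsv(listeners: list[Listener], path: str | Path) -> None:
    rows = [
        (lst.id, cond, srt)
        for lst in listeners
        for cond, srt in sorted(lst.measured_srts.items())
    ]
    pd.DataFrame(rows, columns=["id", "condition", "srt_db"]).to_csv(path, sep="\t", index=False)


def read_measured_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["id"]), {})[str(row["condition"])] = float(row["srt_db"])
    return out


def listeners_from_files(audiogram_csv: str | Path, measured_tsv: str | Path | None = None) -> list[Listener]:
    """Build listeners from an audiogram CSV (group label inferred by nearest template)."""
    audios = read_audiograms_csv(audiogram_csv)
    measured = read_measured_tsv(measured_tsv) if measured_tsv else {}
    listeners = []
    for lid, audio in audios.items():
        mean = (audio.left + audio.right) / 2.0
        group = min(GROUP_TEMPLATES, key=lambda g: float(np.sum((GROUP_TEMPLATES[g] - mean) ** 2)))
        listeners.append(
            Listener(
                id=lid,
                audiogram=audio,
                group=group,
                worse_ear=audio.worse_ear,
                measured_srts=measured.get(lid, {}),
            )
        )
    return listeners
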