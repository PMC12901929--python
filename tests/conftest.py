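"""Shared fixtures: reduced-size engines and listeners.

The solver fixtures run at 22.05 kHz with 1-2 s tokens and few Monte-Carlo
draws so the whole suite stays desk-scale; session scope lets the engines
reuse their scene and curve caches across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bsim.cohort import Listener, group_template_audiogram
from bsim.ec import ECConfig, JitterConfig
from bsim.srt import SolverConfig, SRTEngine

FS = 22050.0


@pytest.fixture(scope="session")
def fast_solver() -> SolverConfig:
    return SolverConfig(sample_rate=FS, token_duration=1.0, n_sentences=1, n_monte_carlo=2)


@pytest.fixture(scope="session")
def fast_engine(fast_solver) -> SRTEngine:
    return SRTEngine(solver=fast_solver, ec=ECConfig(n_monte_carlo=fast_solver.n_monte_carlo))


@pytest.fixture(scope="session")
def det_engine() -> SRTEngine:
    """Jitter-free single-draw engine: fully deterministic curves."""
    solver = SolverConfig(sample_rate=FS, token_duration=1.0, n_sentences=1, n_monte_carlo=1)
    return SRTEngine(solver=solver, jitter=JitterConfig.off(), ec=ECConfig(n_monte_carlo=1))


def make_listener(group: str, worse_ear: str = "left", lid: str | None = None) -> Listener:
    aud = group_template_audiogram(group, jitter_db=0.0, seed=0)
    return Listener(lid or group.lower(), aud, group, worse_ear=worse_ear)


@pytest.fixture(scope="session")
def nh_listener() -> Listener:
    return make_listener("NH")


@pytest.fixture(scope="session")
def nh_predictions(fast_engine, nh_listener):
    """Predicted SRTs for a normal-hearing listener, all three conditions."""
    from bsim.srt import solve_srt

    out = {}
    for cond in ("S0N0", "S0N90", "S0mN90m"):
        curve = fast_engine.sii_vs_snr(nh_listener, cond, seed=7)
        out[cond] = solve_srt(curve, 0.2)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
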