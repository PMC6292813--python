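"""Shared fixtures: synthetic traces and (session-cached) ladder simulations."""

import numpy as np
import pytest

from biopace.ionic_model import VoltageTrace, default_cell_params, simulate
from biopace.ap_metrics import compute_ap_metrics
from biopace.pipeline import Preparation, params_for_preparation


def make_sawtooth_trace(period_ms: float = 200.0, n_beats: int = 12,
                        dt: float = 0.25, mdp: float = -60.0,
                        peak: float = 20.0) -> VoltageTrace:
    """Idealised AP train: slow diastolic ramp + fast upstroke + decay.

    Each cycle: 70% of the period is a linear diastolic ramp from ``mdp``
    upward, then a steep upstroke to ``peak`` and a linear repolarisation
    back to ``mdp``.
    """
    t = np.arange(0.0, period_ms * n_beats, dt)
    phase = (t % period_ms) / period_ms
    v = np.empty_like(t)
    ramp = phase < 0.7
    up = (phase >= 0.7) & (phase < 0.75)
    down = phase >= 0.75
    v[ramp] = mdp + 10.0 * phase[ramp] / 0.7
    # smooth (half-cosine) upstroke so max dv/dt is a single unambiguous sample
    u = (phase[up] - 0.7) / 0.05
    v[up] = (mdp + 10.0) + (peak - mdp - 10.0) * 0.5 * (1.0 - np.cos(np.pi * u))
    v[down] = peak + (mdp - peak) * (phase[down] - 0.75) / 0.25
    return VoltageTrace(t=t, v=v)


@pytest.fixture(scope="session")
def sawtooth_trace() -> VoltageTrace:
    return make_sawtooth_trace()


@pytest.fixture(scope="session")
def san_trace():
    """Limit-cycle SAN simulation shared across tests (expensive)."""
    return simulate(default_cell_params(), 10.0)


@pytest.fixture(scope="session")
def ladder_metrics():
    """AP metrics for each rung of the default ladder (expensive)."""
    out = {}
    for prep in Preparation:
        p = params_for_preparation(prep)
        tr = simulate(p, 10.0)
        out[prep.value] = compute_ap_metrics(tr, discard_beats=20)
    return out
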