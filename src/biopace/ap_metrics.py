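"""Action-potential feature extraction from simulated voltage traces.

Extracts per-beat and per-trace features of spontaneous pacemaker activity:
beating rate, cycle length, diastolic depolarisation (DD) slope and maximum
diastolic potential (MDP).  The beat fiducial is the time of maximum
upstroke velocity (max dv/dt), which is robust to differences in MDP between
parameter sets.  The DD slope is a linear fit of v(t) over a window of each
diastolic interval running from shortly after the MDP to the foot of the
next upstroke (where dv/dt first exceeds a threshold); both window edges are
configurable because published measurements rarely state them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ionic_model import VoltageTrace

__all__ = ["ApMetrics", "detect_beats", "dd_slope", "mdp", "compute_ap_metrics"]


@dataclass
class ApMetrics:
    """Summary features of a spontaneous pacemaking trace.

    rate in beats/min, cycle_length in ms, dd_slope in V/s, mdp in mV.
    """

    rate: float
    cycle_length: float
    dd_slope: float
    mdp: float
    n_beats: int
    per_beat_cl: np.ndarray = field(default_factory=lambda: np.array([]))
    per_beat_dd: np.ndarray = field(default_factory=lambda: np.array([]))
    per_beat_mdp: np.ndarray = field(default_factory=lambda: np.array([]))


def _dvdt(trace: VoltageTrace) -> np.ndarray:
    return np.gradient(trace.v, trace.t)  # mV/ms == V/s


def detect_beats(trace: VoltageTrace, min_upstroke: float = 1.0,
                 min_separation_ms: float = 50.0) -> np.ndarray:
    """Beat fiducial times: one max-dv/dt instant per action potential.

    Parameters
    ----------
    trace : VoltageTrace
    min_upstroke : float
        Minimum upstroke velocity (V/s) for a candidate beat.
    min_separation_ms : float
        Refractory separation between fiducials.

    Returns
    -------
    ndarray of strictly increasing beat times (ms); empty when no beat
    exceeds ``min_upstroke``.
    """
    from scipy.signal import find_peaks

    dvdt = _dvdt(trace)
    if dvdt.size < 3:
        return np.array([])
    dt = float(np.median(np.diff(trace.t)))
    height = max(min_upstroke, 0.33 * float(dvdt.max()))
    idx, _ = find_peaks(dvdt, height=height,
                        distance=max(1, int(round(min_separation_ms / dt))))
    return trace.t[idx]


def mdp(trace: VoltageTrace, beat_times: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum diastolic potential: per-cycle minimum of v between upstrokes.

    Returns (mean MDP, per-cycle MDP array) in mV.
    """
    if len(beat_times) < 2:
        raise ValueError("need >= 2 beats to delimit a full cycle")
    vals = []
    for t0, t1 in zip(beat_times[:-1], beat_times[1:]):
        m = (trace.t > t0) & (trace.t < t1)
        vals.append(float(trace.v[m].min()))
    arr = np.array(vals)
    return float(arr.mean()), arr


def dd_slope(trace: VoltageTrace, beat_times: np.ndarray,
             mdp_offset_ms: float = 5.0,
             upstroke_thresh: float = 0.5) -> tuple[float, np.ndarray]:
    """Diastolic depolarisation slope (V/s), averaged over analysed beats.

    For each diastole the window runs from ``mdp_offset_ms`` after the MDP to
    the first sample where dv/dt exceeds ``upstroke_thresh`` V/s; the slope
    is the least-squares linear fit of v(t) over that window.  Diastoles with
    an empty window are skipped.
    """
    if len(beat_times) < 2:
        raise ValueError("need >= 2 beats for a diastolic interval")
    dvdt = _dvdt(trace)
    slopes = []
    for t0, t1 in zip(beat_times[:-1], beat_times[1:]):
        m = (trace.t > t0) & (trace.t < t1)
        tt, vv, dd = trace.t[m], trace.v[m], dvdt[m]
        if tt.size < 4:
            continue
        i_mdp = int(np.argmin(vv))
        t_start = tt[i_mdp] + mdp_offset_ms
        above = np.nonzero((dd > upstroke_thresh) & (tt > t_start))[0]
        t_end = tt[above[0]] if above.size else t1
        w = (tt >= t_start) & (tt < t_end)
        if np.count_nonzero(w) < 3:
            continue
        slopes.append(float(np.polyfit(tt[w], vv[w], 1)[0]))  # mV/ms == V/s
    if not slopes:
        raise ValueError("no diastolic window could be fit")
    arr = np.array(slopes)
    return float(arr.mean()), arr


def compute_ap_metrics(trace: VoltageTrace, discard_beats: int = 20,
                       min_beats: int = 10,
                       dd_kwargs: dict | None = None) -> ApMetrics:
    """Full feature set on the limit-cycle portion of a trace.

    The first ``discard_beats`` beats are treated as the convergence
    transient and dropped; metrics are computed on the remainder, which must
    contain at least ``min_beats`` beats.
    """
    beats = detect_beats(trace)
    if len(beats) - discard_beats < min_beats:
        raise ValueError(
            f"only {len(beats)} beats detected; need >= {discard_beats + min_beats}"
        )
    beats = beats[discard_beats:]
    cls_ = np.diff(beats)
    cl = float(cls_.mean())
    dd_mean, dd_arr = dd_slope(trace, beats, **(dd_kwargs or {}))
    mdp_mean, mdp_arr = mdp(trace, beats)
    return ApMetrics(
        rate=60000.0 / cl,
        cycle_length=cl,
        dd_slope=dd_mean,
        mdp=mdp_mean,
        n_beats=len(beats),
        per_beat_cl=cls_,
        per_beat_dd=dd_arr,
        per_beat_mdp=mdp_arr,
    )
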