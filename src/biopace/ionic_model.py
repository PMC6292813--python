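"""Single-cell sinoatrial-node (SAN) pacemaker model with an isoform-specific funny current.

The chassis is a compact mouse-type central SAN cell model built from the
standard pacemaking toolkit: an L-type and a T-type Ca2+ current, the rapid
delayed rectifier ``I_Kr``, a transient outward current, the Na+/K+ pump,
the Na+/Ca2+ exchanger, a background Na+ current, and a two-compartment
intracellular Ca2+ subsystem (SERCA uptake into the SR, RYR2-mediated
Ca2+-induced Ca2+ release plus a diastolic leak) so that both the "membrane
clock" and the "Ca2+ clock" contribute to diastolic depolarisation.

Its funny current is not a single lumped conductance: ``I_f`` is the sum of
three independently gated isoform components,

    I_f = I_f,HCN1 + I_f,HCN2 + I_f,HCN4,

each with its own activation midpoint (defaults -75.2 / -92.0 / -91.2 mV for
HCN1 / HCN2 / HCN4), activation time constant (HCN1 fastest, HCN4 slowest)
and maximal conductance (default split 3:1:6), and each carrying both Na+
and K+ ions:

    I_f,iso = g_iso * y_iso * [f_Na (V - E_Na) + (1 - f_Na)(V - E_K)].

Conventions: voltages in mV, time in ms, current densities in pA/pF,
conductances in nS/pF (pA/pF per mV of driving force), concentrations in mM.
Default parameters are calibrated once so that the SAN configuration paces
spontaneously at the reference basal rate (~309 bpm) with a diastolic
depolarisation slope near 0.23 V/s, and are then frozen; see
``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Isoform",
    "TauParams",
    "IfIsoformParams",
    "CellParams",
    "CellState",
    "IfCurrents",
    "VoltageTrace",
    "IVCurve",
    "default_cell_params",
    "steady_state_activation",
    "activation_tau",
    "compute_if",
    "derivatives",
    "simulate",
    "voltage_clamp_iv",
    "initial_state",
]

# physical constants
F = 96485.0          # C/mol
R = 8314.0           # mJ/(mol*K)
T = 310.0            # K
RTF = R * T / F      # ~26.73 mV


class Isoform(str, Enum):
    HCN1 = "HCN1"
    HCN2 = "HCN2"
    HCN4 = "HCN4"


@dataclass
class TauParams:
    """Voltage-dependent activation time constant of one HCN isoform.

    tau(v) = speed * (t_min + amp / (exp((v - v_center)/k_depol)
                                     + exp(-(v - v_center)/k_hyper)))

    A bell-shaped curve peaking near ``v_center``; ``speed`` is the
    isoform-specific multiplicative factor (HCN1 < HCN2 < HCN4).
    """

    speed: float = 1.0
    t_min: float = 25.0      # ms
    amp: float = 250.0       # ms
    v_center: float = -90.0  # mV
    k_depol: float = 15.0    # mV
    k_hyper: float = 20.0    # mV


@dataclass
class IfIsoformParams:
    """Parameters of one isoform component of the funny current.

    ``g_max`` is a conductance density (nS/pF); ``f_na`` is the fraction of
    the isoform current carried by Na+ (the K+ share is ``1 - f_na``), so the
    composite reversal potential is ``f_na*E_Na + (1-f_na)*E_K``.
    """

    isoform: Isoform
    v_half: float            # mV, half-activation (negative)
    slope: float = 9.0       # mV, Boltzmann slope factor
    g_max: float = 0.0       # nS/pF
    tau_params: TauParams = field(default_factory=TauParams)
    f_na: float = 0.38

    def validate(self) -> None:
        if not self.v_half < 0:
            raise ValueError(f"v_half must be negative, got {self.v_half}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")
        if not 0.0 <= self.f_na <= 1.0:
            raise ValueError(f"f_na must be in [0, 1], got {self.f_na}")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


@dataclass
class CellParams:
    """Full parameter set of the single-cell model.

    ``ryr2_scale`` multiplies the SR Ca2+ release and leak rate constants;
    it is the hook through which a measured RYR2 transcript fold-change is
    applied to the Ca2+ clock.
    """

    # membrane
    cm: float = 25.0              # pF
    # maximal conductances, nS/pF
    g_cal: float = 0.35920
    g_cat: float = 0.17868
    g_kr: float = 0.63536
    g_to: float = 0.08273
    g_bna: float = 0.0010
    i_nak_max: float = 0.07981    # pA/pF
    k_ncx: float = 4000.0         # pA/pF scaling of the NCX driving term
    # fixed ionic concentrations, mM
    nao: float = 140.0
    nai: float = 8.0
    ko: float = 5.4
    ki: float = 140.0
    cao: float = 1.8
    # reversal potential of Ca2+ currents (linear driving-force convention)
    e_ca_app: float = 45.0        # mV
    # Ca2+ handling
    v_i: float = 2.0              # pL, effective cytosolic volume
    v_sr: float = 0.2             # pL, effective SR volume
    p_up: float = 0.008           # mM/ms, maximal SERCA uptake
    k_up: float = 0.0006          # mM
    k_rel: float = 0.3            # 1/ms, CICR release rate constant (RYR2)
    k_rel_half: float = 0.0012    # mM, CICR half-activation
    n_rel: float = 2.0
    k_leak: float = 5.0e-4        # 1/ms, diastolic SR leak rate constant
    ryr2_scale: float = 1.0
    beta_i: float = 0.04          # cytosolic rapid-buffering factor
    beta_sr: float = 0.3          # SR rapid-buffering factor
    # funny current, per isoform
    if_isoforms: dict[Isoform, IfIsoformParams] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("g_cal", "g_cat", "g_kr", "g_to", "g_bna", "i_nak_max",
                     "k_ncx", "p_up", "k_rel", "k_leak", "ryr2_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for p in self.if_isoforms.values():
            p.validate()

    @property
    def g_f_total(self) -> float:
        return sum(p.g_max for p in self.if_isoforms.values())

    @property
    def e_na(self) -> float:
        return RTF * math.log(self.nao / self.nai)

    @property
    def e_k(self) -> float:
        return RTF * math.log(self.ko / self.ki)


# reference basal isoform conductance split, HCN1 : HCN2 : HCN4 = 3 : 1 : 6
BASE_ISOFORM_FRACTIONS = {Isoform.HCN1: 0.3, Isoform.HCN2: 0.1, Isoform.HCN4: 0.6}

DEFAULT_V_HALF = {Isoform.HCN1: -75.2, Isoform.HCN2: -92.0, Isoform.HCN4: -91.2}
# activation-speed multipliers preserving the HCN1 < HCN2 < HCN4 kinetic ordering
DEFAULT_TAU_SPEED = {Isoform.HCN1: 0.25, Isoform.HCN2: 1.0, Isoform.HCN4: 2.5}


def default_cell_params(g_f_total: float = 0.09200) -> CellParams:
    """Calibrated SAN default parameters.

    ``g_f_total`` (nS/pF) is distributed over HCN1/HCN2/HCN4 with the 3:1:6
    basal split.
    """
    isoforms = {
        iso: IfIsoformParams(
            isoform=iso,
            v_half=DEFAULT_V_HALF[iso],
            g_max=g_f_total * BASE_ISOFORM_FRACTIONS[iso],
            tau_params=TauParams(speed=DEFAULT_TAU_SPEED[iso]),
        )
        for iso in Isoform
    }
    return CellParams(if_isoforms=isoforms)


# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

ISO_ORDER = (Isoform.HCN1, Isoform.HCN2, Isoform.HCN4)

STATE_NAMES = (
    "v",
    "y_hcn1", "y_hcn2", "y_hcn4",
    "d_cal", "f_cal",
    "d_cat", "f_cat",
    "pa_kr",
    "q_to", "r_to",
    "cai", "casr",
)
N_STATES = len(STATE_NAMES)
_GATE_IDX = slice(1, 11)


@dataclass
class CellState:
    """Named view of the model state vector."""

    v: float
    y: dict[Isoform, float]
    d_cal: float
    f_cal: float
    d_cat: float
    f_cat: float
    pa_kr: float
    q_to: float
    r_to: float
    cai: float
    casr: float

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.v] + [self.y[iso] for iso in ISO_ORDER]
            + [self.d_cal, self.f_cal, self.d_cat, self.f_cat,
               self.pa_kr, self.q_to, self.r_to, self.cai, self.casr]
        )

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "CellState":
        x = np.asarray(x, dtype=float)
        return cls(
            v=float(x[0]),
            y={iso: float(x[1 + i]) for i, iso in enumerate(ISO_ORDER)},
            d_cal=float(x[4]), f_cal=float(x[5]),
            d_cat=float(x[6]), f_cat=float(x[7]),
            pa_kr=float(x[8]), q_to=float(x[9]), r_to=float(x[10]),
            cai=float(x[11]), casr=float(x[12]),
        )


@dataclass
class IfCurrents:
    """Funny-current decomposition at one instant (pA/pF)."""

    by_isoform: dict[Isoform, float]
    na_by_isoform: dict[Isoform, float]
    k_by_isoform: dict[Isoform, float]

    @property
    def total(self) -> float:
        return sum(self.by_isoform.values())


@dataclass
class VoltageTrace:
    """Simulated (t, v) record with optional current traces.

    ``t`` in ms, ``v`` in mV, currents in pA/pF keyed by name.
    """

    t: np.ndarray
    v: np.ndarray
    currents: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        data = {"t_ms": self.t, "v_mV": self.v}
        for k, arr in self.currents.items():
            data[k] = arr
        return pd.DataFrame(data)


@dataclass
class IVCurve:
    """Quasi-steady-state I-V relation of the total funny current."""

    v_test: np.ndarray           # mV
    i_f: np.ndarray              # pA/pF at end of test pulse
    steady: np.ndarray           # bool, |dI/dt| below tolerance at pulse end


# ---------------------------------------------------------------------------
# funny-current gating
# ---------------------------------------------------------------------------

def steady_state_activation(v: float, p: IfIsoformParams) -> float:
    """Boltzmann steady-state activation y_inf(v) = 1/(1+exp((v-v_half)/slope)).

    Monotonically decreasing in ``v`` (hyperpolarisation opens the channel);
    equals 0.5 at ``v_half``.
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp((v - p.v_half) / p.slope))
    return float(out) if out.ndim == 0 else out


def activation_tau(v: float, p: IfIsoformParams) -> float:
    """Voltage-dependent activation time constant (ms), strictly positive."""
    tp = p.tau_params
    v = np.asarray(v, dtype=float)
    out = tp.speed * (
        tp.t_min
        + tp.amp / (np.exp((v - tp.v_center) / tp.k_depol)
                    + np.exp(-(v - tp.v_center) / tp.k_hyper))
    )
    return float(out) if out.ndim == 0 else out


def compute_if(state: CellState, params: CellParams) -> IfCurrents:
    """Per-isoform funny current and its Na+/K+ components (pA/pF).

    Each isoform current is ``g_max * y * [f_na (v-E_Na) + (1-f_na)(v-E_K)]``;
    the Na+ and K+ components sum exactly to the isoform current and the
    isoform currents sum exactly to the total.
    """
    e_na, e_k = params.e_na, params.e_k
    i_na: dict[Isoform, float] = {}
    i_k: dict[Isoform, float] = {}
    tot: dict[Isoform, float] = {}
    for iso in ISO_ORDER:
        p = params.if_isoforms[iso]
        gy = p.g_max * state.y[iso]
        na = gy * p.f_na * (state.v - e_na)
        k = gy * (1.0 - p.f_na) * (state.v - e_k)
        i_na[iso], i_k[iso], tot[iso] = na, k, na + k
    return IfCurrents(by_isoform=tot, na_by_isoform=i_na, k_by_isoform=i_k)


# ---------------------------------------------------------------------------
# gating steady states and time constants of the chassis currents
# ---------------------------------------------------------------------------
# Shapes follow the standard central-SAN formulations; time constants in ms.

def _d_cal_inf(v): return 1.0 / (1.0 + math.exp(-(v + 30.0) / 4.5))
def _f_cal_inf(v): return 1.0 / (1.0 + math.exp((v + 38.0) / 5.0))
def _d_cat_inf(v): return 1.0 / (1.0 + math.exp(-(v + 50.0) / 5.0))
def _f_cat_inf(v): return 1.0 / (1.0 + math.exp((v + 62.0) / 4.5))
def _pa_inf(v): return 1.0 / (1.0 + math.exp(-(v + 21.0) / 7.4))
def _pi_kr(v): return 0.3 + 0.7 / (1.0 + math.exp((v + 28.0) / 10.0))
def _q_inf(v): return 1.0 / (1.0 + math.exp((v + 49.0) / 13.0))
def _r_inf(v): return 1.0 / (1.0 + math.exp(-(v - 2.0) / 13.0))


def _tau_pa(v):
    return 40.0 + 600.0 / (math.exp((v + 35.0) / 12.0)
                           + math.exp(-(v + 35.0) / 12.0))


TAU_D_CAL = 1.5
TAU_F_CAL = 30.0
TAU_D_CAT = 1.5
TAU_F_CAT = 15.0
TAU_Q = 30.0
TAU_R = 3.0
KM_FCA = 0.00035  # mM, Ca2+-dependent inactivation of I_CaL


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _rhs(t: float, x: np.ndarray, p: CellParams,
         iso_arr: tuple) -> np.ndarray:
    (v, y1, y2, y4, d_cal, f_cal, d_cat, f_cat, pa, q, r, cai, casr) = x
    cai = max(cai, 1e-9)

    e_na = RTF * math.log(p.nao / p.nai)
    e_k = RTF * math.log(p.ko / p.ki)

    # funny current, per isoform
    i_f = 0.0
    dy = [0.0, 0.0, 0.0]
    for j, (g, vh, sl, fna, sp, tmin, amp, vc, kd, kh) in enumerate(iso_arr):
        y = (y1, y2, y4)[j]
        i_f += g * y * (fna * (v - e_na) + (1.0 - fna) * (v - e_k))
        y_inf = 1.0 / (1.0 + math.exp((v - vh) / sl))
        tau = sp * (tmin + amp / (math.exp((v - vc) / kd)
                                  + math.exp(-(v - vc) / kh)))
        dy[j] = (y_inf - y) / tau

    # L-type Ca2+ current with Ca2+-dependent inactivation
    f_ca = KM_FCA / (KM_FCA + cai)
    i_cal = p.g_cal * d_cal * f_cal * f_ca * (v - p.e_ca_app)

    # T-type Ca2+ current
    i_cat = p.g_cat * d_cat * f_cat * (v - p.e_ca_app)

    # rapid delayed rectifier
    i_kr = p.g_kr * pa * _pi_kr(v) * (v - e_k)

    # transient outward
    i_to = p.g_to * q * r * (v - e_k)

    # Na+/K+ pump (fixed intracellular Na+)
    i_nak = p.i_nak_max / (1.0 + math.exp(-(v + 60.0) / 40.0))

    # Na+/Ca2+ exchanger (Luo-Rudy-type driving term)
    gam = 0.35
    ef1 = math.exp(gam * v / RTF)
    ef2 = math.exp((gam - 1.0) * v / RTF)
    num = ef1 * p.nai ** 3 * p.cao - ef2 * p.nao ** 3 * cai
    den = (87.5 ** 3 + p.nao ** 3) * (1.38 + p.cao) * (1.0 + 0.1 * ef2)
    i_ncx = p.k_ncx * num / den

    # background Na+
    i_bna = p.g_bna * (v - e_na)

    i_tot = i_f + i_cal + i_cat + i_kr + i_to + i_nak + i_ncx + i_bna

    # Ca2+ subsystem (fluxes in cytosolic mM/ms)
    rel_scale = p.ryr2_scale
    o_rel = cai ** p.n_rel / (cai ** p.n_rel + p.k_rel_half ** p.n_rel)
    j_rel = p.k_rel * rel_scale * o_rel * (casr - cai)
    j_leak = p.k_leak * rel_scale * (casr - cai)
    j_up = p.p_up * cai / (cai + p.k_up)
    # membrane Ca2+ flux: pA/pF * pF / (2 F * pL) -> mM/ms
    j_mem = -(i_cal + i_cat - 2.0 * i_ncx) * p.cm / (2.0 * F * p.v_i)

    dcai = p.beta_i * (j_mem + j_rel + j_leak - j_up)
    dcasr = p.beta_sr * (j_up - j_rel - j_leak) * p.v_i / p.v_sr

    return np.array([
        -i_tot,
        dy[0], dy[1], dy[2],
        (_d_cal_inf(v) - d_cal) / TAU_D_CAL,
        (_f_cal_inf(v) - f_cal) / TAU_F_CAL,
        (_d_cat_inf(v) - d_cat) / TAU_D_CAT,
        (_f_cat_inf(v) - f_cat) / TAU_F_CAT,
        (_pa_inf(v) - pa) / _tau_pa(v),
        (_q_inf(v) - q) / TAU_Q,
        (_r_inf(v) - r) / TAU_R,
        dcai, dcasr,
    ])


def _iso_array(params: CellParams) -> tuple:
    out = []
    for iso in ISO_ORDER:
        p = params.if_isoforms[iso]
        tp = p.tau_params
        out.append((p.g_max, p.v_half, p.slope, p.f_na,
                    tp.speed, tp.t_min, tp.amp, tp.v_center,
                    tp.k_depol, tp.k_hyper))
    return tuple(out)


def derivatives(t: float, state: CellState | np.ndarray,
                params: CellParams) -> np.ndarray:
    """Time derivative of the full state vector.

    Raises ``FloatingPointError`` on a non-finite state (integration
    blow-up), otherwise a total function.
    """
    x = state.to_vector() if isinstance(state, CellState) else np.asarray(state, float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite model state")
    return _rhs(t, x, params, _iso_array(params))


def initial_state(params: CellParams, v0: float = -60.0) -> CellState:
    """A physiologically sensible starting point on the diastolic limb."""
    y = {iso: steady_state_activation(v0, params.if_isoforms[iso]) for iso in ISO_ORDER}
    return CellState(
        v=v0,
        y=y,
        d_cal=_d_cal_inf(v0),
        f_cal=_f_cal_inf(v0),
        d_cat=_d_cat_inf(v0),
        f_cat=_f_cat_inf(v0),
        pa_kr=_pa_inf(v0),
        q_to=_q_inf(v0),
        r_to=_r_inf(v0),
        cai=1.5e-4,
        casr=0.6,
    )


@dataclass
class SolverConfig:
    """Integrator settings: stiff-capable adaptive LSODA, deterministic."""

    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 1.0      # ms
    dt_out: float = 0.25       # ms, output sampling interval
    method: str = "LSODA"


def simulate(params: CellParams, duration: float,
             solver_cfg: SolverConfig | None = None,
             state0: CellState | None = None,
             record_currents: bool = False) -> VoltageTrace:
    """Integrate the model for ``duration`` seconds.

    Parameters
    ----------
    params
        Cell parameter set (validated on entry).
    duration
        Simulated time in seconds (> 0).
    solver_cfg
        Integrator configuration; the default is a stiff-capable adaptive
        solver with rtol 1e-6 / atol 1e-8 and 1 ms maximum step.
    state0
        Optional initial state; default is a diastolic starting point.
    record_currents
        If True the returned trace carries the funny-current decomposition
        and the major membrane currents re-evaluated along the solution.

    Returns
    -------
    VoltageTrace
        Uniformly sampled (t, v[, currents]) record; deterministic for a
        given ``params`` / ``solver_cfg``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0 seconds")
    params.validate()
    cfg = solver_cfg or SolverConfig()
    x0 = (state0 or initial_state(params)).to_vector()
    t_end = duration * 1000.0
    t_eval = np.arange(0.0, t_end + cfg.dt_out / 2, cfg.dt_out)
    iso_arr = _iso_array(params)
    sol = solve_ivp(
        _rhs, (0.0, t_end), x0, t_eval=t_eval,
        args=(params, iso_arr),
        method=cfg.method, rtol=cfg.rtol, atol=cfg.atol,
        max_step=cfg.max_step,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.2f} ms: "
            f"{sol.message}"
        )
    trace = VoltageTrace(t=sol.t, v=sol.y[0])
    if record_currents:
        trace.currents = _currents_along(sol.t, sol.y, params)
    return trace


def _currents_along(t: np.ndarray, y: np.ndarray,
                    params: CellParams) -> dict[str, np.ndarray]:
    e_na, e_k = params.e_na, params.e_k
    v = y[0]
    out: dict[str, np.ndarray] = {}
    total = np.zeros_like(v)
    for j, iso in enumerate(ISO_ORDER):
        p = params.if_isoforms[iso]
        gy = p.g_max * y[1 + j]
        i_iso = gy * (p.f_na * (v - e_na) + (1 - p.f_na) * (v - e_k))
        out[f"i_f_{iso.value.lower()}"] = i_iso
        total = total + i_iso
    out["i_f_total"] = total
    f_ca = KM_FCA / (KM_FCA + np.maximum(y[11], 1e-9))
    out["i_cal"] = params.g_cal * y[4] * y[5] * f_ca * (v - params.e_ca_app)
    pi_kr = 0.3 + 0.7 / (1.0 + np.exp((v + 28.0) / 10.0))
    out["i_kr"] = params.g_kr * y[8] * pi_kr * (v - e_k)
    return out


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def voltage_clamp_iv(params: CellParams,
                     protocol: Sequence[tuple[float, float, float]],
                     steady_tol: float = 1e-4) -> IVCurve:
    """Simulated voltage-clamp I-V relation of the total funny current.

    For each protocol step ``(hold_mV, test_mV, duration_ms)`` the isoform
    gates are equilibrated at the holding potential, relaxed exponentially at
    the test potential for the pulse duration (the gating ODEs are linear at
    fixed voltage, so the relaxation is closed-form), and the end-of-pulse
    total ``I_f`` density (pA/pF, i.e. normalised to capacitance) is
    reported.  Pulses whose end-of-pulse ``|dI/dt|`` exceeds ``steady_tol``
    (pA/pF per ms) are flagged as not having reached steady state.

    Parameters
    ----------
    params : CellParams
    protocol : list of (hold_mV, test_mV, duration_ms)
    steady_tol : float, optional

    Returns
    -------
    IVCurve
    """
    if len(protocol) == 0:
        raise ValueError("protocol must be nonempty")
    params.validate()
    e_na, e_k = params.e_na, params.e_k
    v_tests, currents, steady = [], [], []
    for hold, test, dur in protocol:
        if dur <= 0:
            raise ValueError("pulse duration must be positive")
        i_end = 0.0
        didt = 0.0
        for iso in ISO_ORDER:
            p = params.if_isoforms[iso]
            y0 = steady_state_activation(hold, p)
            y_inf = steady_state_activation(test, p)
            tau = activation_tau(test, p)
            y_end = y_inf + (y0 - y_inf) * math.exp(-dur / tau)
            drive = p.f_na * (test - e_na) + (1 - p.f_na) * (test - e_k)
            i_end += p.g_max * y_end * drive
            didt += p.g_max * drive * (y_inf - y_end) / tau
        v_tests.append(test)
        currents.append(i_end)
        steady.append(abs(didt) <= steady_tol)
    return IVCurve(v_test=np.array(v_tests), i_f=np.array(currents),
                   steady=np.array(steady))


def composite_reversal(p: IfIsoformParams, e_na: float, e_k: float) -> float:
    """Reversal potential of one isoform current, f_na-weighted."""
    return p.f_na * e_na + (1.0 - p.f_na) * e_k


def scaled_params(params: CellParams, factors: dict[Isoform, float],
                  ryr2_factor: float | None = None) -> CellParams:
    """Return a copy with per-isoform g_max multiplied by ``factors``.

    ``ryr2_factor``, if given, multiplies ``ryr2_scale``.
    """
    new_iso = {
        iso: replace(params.if_isoforms[iso],
                     g_max=params.if_isoforms[iso].g_max * factors.get(iso, 1.0))
        for iso in ISO_ORDER
    }
    new = replace(params, if_isoforms=new_iso)
    if ryr2_factor is not None:
        if ryr2_factor <= 0:
            raise ValueError("ryr2_factor must be positive")
        new = replace(new, ryr2_scale=params.ryr2_scale * ryr2_factor)
    return new
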