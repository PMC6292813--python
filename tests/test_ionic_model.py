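"""Unit and property tests of the SAN cell model and its isoform-split funny current."""

import math
from dataclasses import replace

import numpy as np
import pytest

from biopace.ionic_model import (
    BASE_ISOFORM_FRACTIONS,
    CellParams,
    IfIsoformParams,
    Isoform,
    SolverConfig,
    TauParams,
    activation_tau,
    compute_if,
    default_cell_params,
    derivatives,
    initial_state,
    simulate,
    steady_state_activation,
    voltage_clamp_iv,
    scaled_params,
)
from biopace.ap_metrics import compute_ap_metrics, detect_beats


def iso_params(iso=Isoform.HCN1, **kw):
    defaults = dict(v_half=-75.2, slope=9.0, g_max=0.1)
    defaults.update(kw)
    return IfIsoformParams(isoform=iso, **defaults)


class TestSteadyStateActivation:
    def test_half_activation_at_midpoint(self):
        # HCN1 midpoint -75.2 mV by construction of the default parameters
        p = default_cell_params().if_isoforms[Isoform.HCN1]
        assert steady_state_activation(-75.2, p) == pytest.approx(0.5, abs=1e-12)

    def test_saturation_limits(self):
        p = iso_params()
        assert steady_state_activation(200.0, p) < 1e-10
        assert steady_state_activation(-300.0, p) == pytest.approx(1.0, abs=1e-10)

    def test_quarter_activation_closed_form(self):
        # Boltzmann: y(v_half + slope*ln 3) = 1/(1+3) = 0.25
        p = iso_params()
        v = p.v_half + p.slope * math.log(3.0)
        assert steady_state_activation(v, p) == pytest.approx(0.25, rel=1e-12)

    def test_monotone_decreasing_and_bounded(self):
        p = iso_params()
        v = np.linspace(-200.0, 100.0, 2001)
        y = steady_state_activation(v, p)
        assert np.all((y >= 0.0) & (y <= 1.0))
        assert np.all(np.diff(y) < 0)


class TestActivationTau:
    def test_positive_everywhere(self):
        p = iso_params()
        v = np.linspace(-150.0, 50.0, 401)
        assert np.all(activation_tau(v, p) > 0)

    def test_isoform_kinetic_ordering_at_diastolic_potentials(self):
        # HCN1 activates fastest, HCN4 slowest
        params = default_cell_params().if_isoforms
        for v in (-90.0, -70.0, -60.0):
            t1 = activation_tau(v, params[Isoform.HCN1])
            t2 = activation_tau(v, params[Isoform.HCN2])
            t4 = activation_tau(v, params[Isoform.HCN4])
            assert t1 < t2 < t4

    def test_continuity_dense_grid(self):
        p = iso_params()
        v = np.arange(-120.0, 0.0, 0.1)
        tau = activation_tau(v, p)
        rel_jump = np.abs(np.diff(tau)) / tau[:-1]
        assert rel_jump.max() < 0.10


class TestComputeIf:
    def test_zero_conductance_gives_zero_total(self):
        p = default_cell_params()
        for ip in p.if_isoforms.values():
            ip.g_max = 0.0
        s = initial_state(p)
        assert compute_if(s, p).total == 0.0

    def test_zero_driving_force_at_composite_reversal(self):
        p = default_cell_params()
        ip = p.if_isoforms[Isoform.HCN1]
        e_rev = ip.f_na * p.e_na + (1 - ip.f_na) * p.e_k
        s = initial_state(p, v0=-60.0)
        s.v = e_rev
        # same f_na for all isoforms -> same composite reversal
        assert compute_if(s, p).total == pytest.approx(0.0, abs=1e-12)

    def test_component_conservation_exact(self):
        p = default_cell_params()
        s = initial_state(p, v0=-72.0)
        cur = compute_if(s, p)
        for iso in Isoform:
            assert cur.by_isoform[iso] == cur.na_by_isoform[iso] + cur.k_by_isoform[iso]
        assert cur.total == sum(cur.na_by_isoform[i] + cur.k_by_isoform[i]
                                for i in Isoform)

    def test_linearity_in_g_max(self):
        p = default_cell_params()
        s = initial_state(p, v0=-80.0)
        base = compute_if(s, p)
        p2 = scaled_params(p, {Isoform.HCN2: 2.0})
        doubled = compute_if(s, p2)
        assert doubled.by_isoform[Isoform.HCN2] == pytest.approx(
            2 * base.by_isoform[Isoform.HCN2], rel=1e-12)
        for iso in (Isoform.HCN1, Isoform.HCN4):
            assert doubled.by_isoform[iso] == base.by_isoform[iso]


class TestDerivatives:
    def test_gate_fixed_point(self):
        # gates initialised at their steady state for v0 -> zero gate derivative
        p = default_cell_params()
        s = initial_state(p, v0=-55.0)
        dx = derivatives(0.0, s, p)
        # indices 1..10 are gating variables
        assert np.allclose(dx[1:11], 0.0, atol=1e-12)

    def test_nonfinite_state_rejected(self):
        p = default_cell_params()
        x = initial_state(p).to_vector()
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            derivatives(0.0, x, p)

    def test_dvdt_positive_on_diastolic_limb(self, san_trace):
        beats = detect_beats(san_trace)
        t0, t1 = beats[-2], beats[-1]
        m = (san_trace.t > t0) & (san_trace.t < t1)
        tt, vv = san_trace.t[m], san_trace.v[m]
        i_mdp = np.argmin(vv)
        # mid-diastole: halfway between MDP and the next upstroke
        mid = (tt[i_mdp] + t1) / 2
        j = np.searchsorted(tt, mid)
        dvdt = np.gradient(vv, tt)
        assert dvdt[j] > 0


class TestSimulate:
    def test_spontaneous_rate_near_basal(self, san_trace):
        m = compute_ap_metrics(san_trace, discard_beats=20)
        assert 250.0 < m.rate < 370.0

    def test_zero_funny_current_slows_rate(self, san_trace):
        m_def = compute_ap_metrics(san_trace, discard_beats=20)
        p0 = default_cell_params()
        for ip in p0.if_isoforms.values():
            ip.g_max = 0.0
        tr0 = simulate(p0, 12.0)
        beats = detect_beats(tr0)
        if len(beats) >= 25:
            m0 = compute_ap_metrics(tr0, discard_beats=15, min_beats=5)
            assert m0.rate < m_def.rate
        else:
            # funny-current-free cell failed to sustain comparable pacing at all
            assert len(beats) < m_def.n_beats

    def test_deterministic_repeat(self):
        p = default_cell_params()
        a = simulate(p, 2.0)
        b = simulate(p, 2.0)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.v, b.v)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            simulate(default_cell_params(), 0.0)


class TestRateProperties:
    @pytest.mark.parametrize("scales", [np.linspace(0.5, 2.0, 7)])
    def test_rate_nondecreasing_in_uniform_gf_scale(self, scales):
        rates = []
        for s in scales:
            p = default_cell_params()
            p = scaled_params(p, {iso: s for iso in Isoform})
            m = compute_ap_metrics(simulate(p, 8.0), discard_beats=15, min_beats=5)
            rates.append(m.rate)
        rates = np.array(rates)
        # nondecreasing up to beat-detection quantisation
        assert np.all(np.diff(rates) > -1.5)

    def test_solver_tolerance_robustness(self):
        p = default_cell_params()
        m6 = compute_ap_metrics(
            simulate(p, 8.0, SolverConfig(rtol=1e-6, atol=1e-8)),
            discard_beats=15, min_beats=5)
        m8 = compute_ap_metrics(
            simulate(p, 8.0, SolverConfig(rtol=1e-8, atol=1e-10)),
            discard_beats=15, min_beats=5)
        assert abs(m6.rate - m8.rate) / m8.rate < 0.005

    def test_limit_equivalence_identical_isoforms(self):
        # three identical isoforms sharing total g == one lumped current
        g_tot = default_cell_params().g_f_total
        shared = dict(v_half=-85.0, slope=9.0)

        def with_split(fractions):
            q = default_cell_params()
            for iso, ip in q.if_isoforms.items():
                q.if_isoforms[iso] = replace(
                    ip, v_half=shared["v_half"], slope=shared["slope"],
                    tau_params=TauParams(speed=1.0),
                    g_max=g_tot * fractions[iso])
            return q
        p_a = with_split({Isoform.HCN1: 1.0, Isoform.HCN2: 0.0, Isoform.HCN4: 0.0})
        p_b = with_split(BASE_ISOFORM_FRACTIONS)
        m_a = compute_ap_metrics(simulate(p_a, 8.0), discard_beats=15, min_beats=5)
        m_b = compute_ap_metrics(simulate(p_b, 8.0), discard_beats=15, min_beats=5)
        assert m_a.rate == pytest.approx(m_b.rate, rel=1e-3)


class TestVoltageClampIV:
    def test_reversal_potential_zero_current(self):
        p = default_cell_params()
        ip = p.if_isoforms[Isoform.HCN1]
        e_rev = ip.f_na * p.e_na + (1 - ip.f_na) * p.e_k
        curve = voltage_clamp_iv(p, [(-40.0, e_rev, 3000.0)])
        assert abs(curve.i_f[0]) < 1e-9

    def test_monotone_magnitude_below_minus60(self):
        p = default_cell_params()
        vs = np.arange(-120.0, -59.0, 5.0)
        curve = voltage_clamp_iv(p, [(-35.0, v, 4000.0) for v in vs])
        mag = np.abs(curve.i_f)
        assert np.all(np.diff(mag) < 0)  # magnitude shrinks toward -60

    def test_scaled_down_params_smaller_current_everywhere(self):
        p = default_cell_params()
        p_small = scaled_params(p, {iso: 0.4 for iso in Isoform})
        vs = np.arange(-120.0, -59.0, 10.0)
        proto = [(-35.0, v, 4000.0) for v in vs]
        big = voltage_clamp_iv(p, proto)
        small = voltage_clamp_iv(p_small, proto)
        assert np.all(np.abs(small.i_f) < np.abs(big.i_f))

    def test_unreached_steady_state_flagged(self):
        p = default_cell_params()
        curve = voltage_clamp_iv(p, [(-35.0, -100.0, 1.0)])
        assert not curve.steady[0]

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            voltage_clamp_iv(default_cell_params(), [])
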