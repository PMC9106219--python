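"""Membrane/gating equations, protocol simulation and solver correctness."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nonspike as ns
from nonspike.model import total_membrane_current

from conftest import sample_valid_params


# ---------------------------------------------------------------------------
# Boltzmann gate


@pytest.mark.parametrize("V, V_half, k, expected", [
    (-45.0, -45.0, 5.0, 0.5),                       # x_inf(V_half) = 1/2
    (-40.0, -45.0, 5.0, 1 / (1 + math.exp(-1))),    # V = V_half + k, k > 0
    (-50.0, -45.0, -5.0, 1 / (1 + math.exp(-1))),   # V = V_half + k, k < 0
])
def test_boltzmann_closed_form(V, V_half, k, expected):
    assert ns.boltzmann(V, V_half, k) == pytest.approx(expected, abs=1e-12)


def test_boltzmann_monotonicity():
    V = np.linspace(-100, 40, 200)
    act = ns.boltzmann(V, -45.0, 5.0)
    inact = ns.boltzmann(V, -45.0, -5.0)
    assert np.all(np.diff(act) > 0)
    assert np.all(np.diff(inact) < 0)
    assert ns.boltzmann(-80, -45, -5) > ns.boltzmann(-10, -45, -5)


def test_boltzmann_zero_slope_rejected():
    with pytest.raises(ns.InvalidParameterError):
        ns.boltzmann(-45.0, -45.0, 0.0)


# ---------------------------------------------------------------------------
# channel current


@pytest.mark.parametrize("g, E, gates, exps, V, expected", [
    (3.0, -80.0, [0.7], [1], -80.0, 0.0),          # reversal potential
    (2.0, 0.0, [0.5], [1], 10.0, 10.0),            # g * m * (V - E)
    (5.0, -80.0, [0.0, 0.9], [1, 1], -30.0, 0.0),  # closed gate blocks
    (1.5, -60.0, [], [], -40.0, 30.0),             # leak: no gates
])
def test_channel_current_examples(g, E, gates, exps, V, expected):
    assert ns.channel_current(g, E, gates, exps, V) == pytest.approx(expected)


def test_channel_current_sign_reverses_at_reversal():
    below = ns.channel_current(2.0, -80.0, [0.5], [1], -90.0)
    above = ns.channel_current(2.0, -80.0, [0.5], [1], -70.0)
    assert below < 0 < above


# ---------------------------------------------------------------------------
# model composition


def test_build_model_compositions(rim_model, afd_model, aiy_model):
    assert rim_model.channel_names() == ("Ca,p", "Kir", "K,t", "L")
    assert afd_model.channel_names() == ("Ca,p", "Kir", "K,t", "L")
    assert aiy_model.channel_names() == ("Ca,t", "Kir", "K,p", "L")
    for model in (rim_model, aiy_model):
        dyn = model.dynamic_gates()
        assert len(dyn) == 2
        assert {g.role for g in dyn} == {"activation", "inactivation"}
    # transient channel carries the dynamic pair; leak has no gates
    assert rim_model.channels[2].gates[0].kinetics == "dynamic"
    assert aiy_model.channels[0].gates[0].kinetics == "dynamic"
    assert rim_model.channels[3].gates == ()


def test_build_model_unknown_class():
    with pytest.raises(ValueError):
        ns.build_model("XYZ")


# ---------------------------------------------------------------------------
# right-hand side


def test_rhs_vanishes_at_equilibrium(rim_model, near_linear_truth):
    p = near_linear_truth.params
    V_star = ns.find_equilibria(p, rim_model, 0.0)[0].V_star
    state = [V_star,
             ns.boltzmann(V_star, p.V_half_m, p.k_m),
             ns.boltzmann(V_star, p.V_half_h, p.k_h)]
    I = ns.steady_state_current(p, rim_model, V_star)
    assert np.all(np.abs(ns.model_rhs(state, p, rim_model, I)) < 1e-9)


def test_rhs_leak_only_reduction(rim_model, leak_only):
    dV, dm, dh = ns.model_rhs([-40.0, 0.3, 0.7], leak_only, rim_model, 5.0)
    expected = (-0.5 * (-40.0 - (-60.0)) + 5.0) / 1.0
    assert dV == pytest.approx(expected)


def test_rhs_matches_hand_assembled_sum(rim_model):
    # independent term-by-term evaluation at (V=-60, m=0, h=1, I=0)
    p = ns.ParameterVector(g_Ca=1.2, g_Kir=0.8, g_K=2.0, g_L=0.3,
                           E_Ca=110.0, E_K=-85.0, E_L=-55.0,
                           V_half_p=-35.0, k_p=7.0,
                           V_half_Kir=-75.0, k_Kir=-9.0,
                           V_half_m=-28.0, k_m=11.0,
                           V_half_h=-50.0, k_h=-7.0,
                           tau_m=1.5, tau_h=2.5, C=2.0)
    V, m, h = -60.0, 0.0, 1.0
    sig = lambda vh, k: 1.0 / (1.0 + math.exp((vh - V) / k))
    I_cap = 1.2 * sig(-35.0, 7.0) * (V - 110.0)
    I_kir = 0.8 * sig(-75.0, -9.0) * (V - (-85.0))
    I_kt = 2.0 * m * h * (V - (-85.0))
    I_l = 0.3 * (V - (-55.0))
    dV_expected = -(I_cap + I_kir + I_kt + I_l) / 2.0
    dm_expected = (sig(-28.0, 11.0) - m) / 1.5
    dh_expected = (sig(-50.0, -7.0) - h) / 2.5
    dV, dm, dh = ns.model_rhs([V, m, h], p, rim_model, 0.0)
    assert dV == pytest.approx(dV_expected, rel=1e-12)
    assert dm == pytest.approx(dm_expected, rel=1e-12)
    assert dh == pytest.approx(dh_expected, rel=1e-12)


@pytest.mark.parametrize("bad", [{"C": 0.0}, {"C": -1.0}, {"tau_m": 0.0},
                                 {"tau_h": -2.0}])
def test_rhs_rejects_degenerate_parameters(rim_model, bad):
    p = ns.ParameterVector().replace(**bad)
    with pytest.raises(ns.InvalidParameterError):
        ns.model_rhs([-60.0, 0.5, 0.5], p, rim_model, 0.0)


# ---------------------------------------------------------------------------
# current clamp


def test_leak_only_matches_rc_closed_form(rim_model, leak_only):
    proto = ns.StimulusProtocol(currents=(10.0,), span=50.0, dt_out=0.01)
    trace = ns.simulate_current_clamp(rim_model, leak_only, proto, V0=-60.0)[10.0]
    t = proto.time_grid()
    g, C, E, I, V0 = 0.5, 1.0, -60.0, 10.0, -60.0
    analytic = E + I / g + (V0 - E - I / g) * np.exp(-g * t / C)
    assert np.max(np.abs(trace - analytic)) < 0.01
    # and the asymptote is E_L + I/g_L once several membrane time constants pass
    tail = t >= 10 * C / g
    assert np.max(np.abs(trace[tail] - (E + I / g))) < 0.01


def test_flat_trace_when_started_at_equilibrium(rim_model, near_linear_truth):
    p = near_linear_truth.params
    I = 5.0
    eqs = ns.find_equilibria(p, rim_model, I)
    V_star = eqs[0].V_star
    p_eq = p.replace(m0=float(ns.boltzmann(V_star, p.V_half_m, p.k_m)),
                     h0=float(ns.boltzmann(V_star, p.V_half_h, p.k_h)))
    proto = ns.StimulusProtocol(currents=(I,), span=10.0, dt_out=0.04)
    trace = ns.simulate_current_clamp(rim_model, p_eq, proto, V0=V_star)[I]
    assert np.max(np.abs(trace - V_star)) < 1e-6


def test_simulation_is_deterministic(rim_model, near_linear_truth, short_protocol):
    proto = ns.StimulusProtocol(currents=(0.0, 20.0), span=10.0, dt_out=0.04)
    a = ns.simulate_current_clamp(rim_model, near_linear_truth.params, proto, V0=-65.0)
    b = ns.simulate_current_clamp(rim_model, near_linear_truth.params, proto, V0=-65.0)
    for I in proto.currents:
        assert np.array_equal(a[I], b[I])


def _rk4_rim(params, I, V0, span, h):
    """Independent fixed-step RK4 for the RIM-class composition, with the
    right-hand side assembled from scratch (not via the package's rhs)."""
    p = params

    def sig(V, vh, k):
        return 1.0 / (1.0 + math.exp((vh - V) / k))

    def f(y):
        V, m, hh = y
        I_tot = (p.g_Ca * sig(V, p.V_half_p, p.k_p) * (V - p.E_Ca)
                 + p.g_Kir * sig(V, p.V_half_Kir, p.k_Kir) * (V - p.E_K)
                 + p.g_K * m * hh * (V - p.E_K)
                 + p.g_L * (V - p.E_L))
        return np.array([(-I_tot + I) / p.C,
                         (sig(V, p.V_half_m, p.k_m) - m) / p.tau_m,
                         (sig(V, p.V_half_h, p.k_h) - hh) / p.tau_h])

    n = int(round(span / h))
    y = np.array([V0, p.m0, p.h0])
    out = [y.copy()]
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


def test_adaptive_solver_matches_rk4_oracle(rim_model, near_linear_truth):
    p = near_linear_truth.params
    span, h = 5.0, 1e-4
    for I in (0.0, 20.0):
        proto = ns.StimulusProtocol(currents=(I,), span=span, dt_out=0.05)
        trace = ns.simulate_current_clamp(rim_model, p, proto, V0=-65.0)[I]
        oracle = _rk4_rim(p, I, -65.0, span, h)
        idx = (proto.time_grid() / h).round().astype(int)
        assert np.max(np.abs(trace - oracle[idx, 0])) < 0.01


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_gate_variables_stay_in_unit_interval(seed):
    """m(t), h(t) in [0,1] along any trajectory of an in-bounds model."""
    bounds = ns.default_bounds()
    rng = np.random.default_rng(seed)
    params = sample_valid_params(bounds, rng, 1)[0]
    model = ns.build_model("RIM")
    proto = ns.StimulusProtocol(currents=(10.0,), span=100.0, dt_out=0.5)
    _, m, h = ns.simulate_current_clamp(model, params, proto, V0=-60.0,
                                        return_gates=True)[10.0]
    assert np.all((m >= -1e-9) & (m <= 1 + 1e-9))
    assert np.all((h >= -1e-9) & (h <= 1 + 1e-9))


# ---------------------------------------------------------------------------
# voltage clamp


def test_leak_only_clamp_current_constant(rim_model, leak_only):
    t, I_tr = ns.simulate_voltage_clamp(rim_model, leak_only, V_H=-40.0,
                                        duration=5.0)
    assert np.allclose(I_tr, 0.5 * (-40.0 - (-60.0)), atol=1e-9)


def test_clamp_constant_when_gates_start_at_equilibrium(rim_model,
                                                        near_linear_truth):
    p = near_linear_truth.params
    V_H = -30.0
    m_eq = float(ns.boltzmann(V_H, p.V_half_m, p.k_m))
    h_eq = float(ns.boltzmann(V_H, p.V_half_h, p.k_h))
    t, I_tr = ns.simulate_voltage_clamp(rim_model, p, V_H, duration=5.0,
                                        m_init=m_eq, h_init=h_eq)
    assert np.max(np.abs(I_tr - I_tr[0])) < 1e-6


def test_clamp_asymptote_equals_analytic_steady_state(rim_model, bounds):
    """Simulated clamp currents converge to the analytic curve for random
    in-bounds models across the holding-voltage grid (rel. err < 1e-6)."""
    rng = np.random.default_rng(42)
    V_grid = np.arange(-100.0, 51.0, 10.0)
    for p in sample_valid_params(bounds, rng, 20):
        duration = 200.0 * max(p.tau_m, p.tau_h)
        for V_H in V_grid:
            t, I_tr = ns.simulate_voltage_clamp(rim_model, p, V_H,
                                                duration=duration,
                                                dt_out=duration / 4)
            ref = ns.steady_state_current(p, rim_model, V_H)
            assert abs(I_tr[-1] - ref) / (1 + abs(ref)) < 1e-6
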