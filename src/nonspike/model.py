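"""Conductance-based models (CBMs) of non-spiking neurons.

The membrane equation is

    C dV/dt = -sum_ion I_ion + I,      I_ion = g_ion * m^a * h^b * (V - E_ion)

with gating variables relaxing to a Boltzmann equilibrium,

    dx/dt = (x_inf(V) - x) / tau_x,    x_inf(V) = 1 / (1 + exp((V_half - V) / k)).

Units used throughout the package: mV (voltage), pA (current), nS (conductance),
ds (decisecond; a 5 s stimulus span is 50 ds).  Capacitance is expressed in the
consistent derived unit pA*ds/mV (= nS*ds) so that the membrane equation holds
without conversion factors.

Two model classes are provided, reflecting the channel compositions identified
for the three C. elegans neurons under study: RIM and AFD carry a persistent
calcium current, an inward-rectifier potassium current, a transient potassium
current and a leak (I_Ca,p + I_Kir + I_K,t + I_L); AIY carries a transient
calcium current, inward rectifier, persistent potassium current and leak
(I_Ca,t + I_Kir + I_K,p + I_L).  In either case exactly one dynamic activation
gate (m) and one dynamic inactivation gate (h) exist — both on the transient
channel — while the persistent and Kir activations are instantaneous Boltzmann
functions of the voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "NeuronModel",
    "ParameterVector",
    "ModelState",
    "StimulusProtocol",
    "PARAM_NAMES",
    "SS_PARAM_NAMES",
    "boltzmann",
    "channel_current",
    "model_rhs",
    "build_model",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "InvalidParameterError",
    "IntegrationFailureError",
]


class InvalidParameterError(ValueError):
    """A parameter violates a structural precondition (e.g. k = 0, C <= 0)."""


class IntegrationFailureError(RuntimeError):
    """The ODE solver failed to produce a trajectory."""


# Flat genome layout shared by both model classes (D = 20).
PARAM_NAMES: tuple[str, ...] = (
    "g_Ca", "g_Kir", "g_K", "g_L",
    "E_Ca", "E_K", "E_L",
    "V_half_p", "k_p",          # persistent-channel activation (instantaneous)
    "V_half_Kir", "k_Kir",      # Kir activation (instantaneous, k < 0)
    "V_half_m", "k_m",          # transient-channel activation m (dynamic)
    "V_half_h", "k_h",          # transient-channel inactivation h (dynamic)
    "tau_m", "tau_h",
    "C",
    "m0", "h0",
)

#: Steady-state-relevant subset theta_SS (everything except tau_m, tau_h, C, m0, h0).
SS_PARAM_NAMES: tuple[str, ...] = PARAM_NAMES[:15]

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


def boltzmann(V, V_half: float, k: float):
    """Boltzmann open probability x_inf(V) = 1 / (1 + exp((V_half - V)/k)).

    Strictly increasing in V for k > 0 (activation) and strictly decreasing
    for k < 0 (inactivation); x_inf(V_half) = 1/2.
    """
    if k == 0:
        raise InvalidParameterError("Boltzmann slope factor k must be nonzero")
    return expit((np.asarray(V, dtype=float) - V_half) / k)


def channel_current(g: float, E: float, gate_values: Sequence[float],
                    exponents: Sequence[int], V):
    """Single-channel current g * prod(gate^exponent) * (V - E), in pA."""
    V = np.asarray(V, dtype=float)
    open_frac = 1.0
    for x, a in zip(gate_values, exponents):
        if a != 0:
            open_frac = open_frac * np.asarray(x, dtype=float) ** a
    return g * open_frac * (V - E)


@dataclass(frozen=True)
class GateSpec:
    """One gating particle of an ion channel.

    ``param_key`` selects which (V_half, k) pair of the parameter vector the
    gate reads ('p', 'kir', 'm' or 'h'); dynamic gates additionally carry the
    matching time constant and a slot in the model state.
    """

    role: Literal["activation", "inactivation"]
    kinetics: Literal["instantaneous", "dynamic"]
    exponent: int
    param_key: Literal["p", "kir", "m", "h"]

    def __post_init__(self):
        if self.exponent < 1:
            raise InvalidParameterError("gate exponent must be a positive integer")

    def equilibrium(self, V, params: "ParameterVector"):
        V_half, k = params.gate_params(self.param_key)
        return boltzmann(V, V_half, k)


@dataclass(frozen=True)
class ChannelSpec:
    """An ion channel: a named conductance, a reversal potential and gates."""

    name: str
    reversal_key: Literal["E_Ca", "E_K", "E_L"]
    conductance_key: Literal["g_Ca", "g_Kir", "g_K", "g_L"]
    gates: tuple[GateSpec, ...] = ()


@dataclass(frozen=True)
class NeuronModel:
    """Fixed channel composition for one neuron class (RIM, AIY or AFD)."""

    neuron_class: str
    channels: tuple[ChannelSpec, ...]

    def dynamic_gates(self) -> tuple[GateSpec, ...]:
        return tuple(g for ch in self.channels for g in ch.gates
                     if g.kinetics == "dynamic")

    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)


def build_model(neuron_class: str) -> NeuronModel:
    """Return the channel composition for a neuron class.

    RIM and AFD share the I_Ca,p + I_Kir + I_K,t + I_L composition; AIY uses
    I_Ca,t + I_Kir + I_K,p + I_L.  The transient channel carries the two
    dynamic gates (m, h); all other gates are instantaneous.
    """
    kir = ChannelSpec("Kir", "E_K", "g_Kir", (
        GateSpec("activation", "instantaneous", 1, "kir"),))
    leak = ChannelSpec("L", "E_L", "g_L", ())
    m_gate = GateSpec("activation", "dynamic", 1, "m")
    h_gate = GateSpec("inactivation", "dynamic", 1, "h")
    if neuron_class in ("RIM", "AFD"):
        channels = (
            ChannelSpec("Ca,p", "E_Ca", "g_Ca", (
                GateSpec("activation", "instantaneous", 1, "p"),)),
            kir,
            ChannelSpec("K,t", "E_K", "g_K", (m_gate, h_gate)),
            leak,
        )
    elif neuron_class == "AIY":
        channels = (
            ChannelSpec("Ca,t", "E_Ca", "g_Ca", (m_gate, h_gate)),
            kir,
            ChannelSpec("K,p", "E_K", "g_K", (
                GateSpec("activation", "instantaneous", 1, "p"),)),
            leak,
        )
    else:
        raise ValueError(f"unknown neuron class: {neuron_class!r} "
                         "(expected RIM, AIY or AFD)")
    return NeuronModel(neuron_class, channels)


@dataclass
class ParameterVector:
    """The 20 free parameters of a non-spiking CBM (layout in PARAM_NAMES).

    Conductances in nS, potentials in mV, time constants in ds, capacitance in
    pA*ds/mV, initial gate states dimensionless in [0, 1].
    """

    g_Ca: float = 1.0
    g_Kir: float = 1.0
    g_K: float = 1.0
    g_L: float = 0.3
    E_Ca: float = 100.0
    E_K: float = -80.0
    E_L: float = -60.0
    V_half_p: float = -30.0
    k_p: float = 8.0
    V_half_Kir: float = -70.0
    k_Kir: float = -10.0
    V_half_m: float = -25.0
    k_m: float = 10.0
    V_half_h: float = -45.0
    k_h: float = -8.0
    tau_m: float = 1.0
    tau_h: float = 2.0
    C: float = 1.0
    m0: float = 0.5
    h0: float = 0.5

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} components, got {arr.shape}")
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, arr)})

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterVector":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **kwargs) -> "ParameterVector":
        return replace(self, **kwargs)

    def gate_params(self, key: str) -> tuple[float, float]:
        return {
            "p": (self.V_half_p, self.k_p),
            "kir": (self.V_half_Kir, self.k_Kir),
            "m": (self.V_half_m, self.k_m),
            "h": (self.V_half_h, self.k_h),
        }[key]

    def ss_array(self) -> np.ndarray:
        """The theta_SS subset (steady-state-relevant, D_SS = 15)."""
        return self.to_array()[:15]

    def validate(self) -> None:
        if self.C <= 0:
            raise InvalidParameterError("capacitance C must be positive")
        if self.tau_m <= 0 or self.tau_h <= 0:
            raise InvalidParameterError("gate time constants must be positive")
        if self.k_p <= 0 or self.k_m <= 0:
            raise InvalidParameterError("activation slopes k_p, k_m must be > 0")
        if self.k_Kir >= 0 or self.k_h >= 0:
            raise InvalidParameterError("k_Kir and k_h must be < 0")
        if not (0.0 <= self.m0 <= 1.0 and 0.0 <= self.h0 <= 1.0):
            raise InvalidParameterError("initial gate states must lie in [0, 1]")


@dataclass
class ModelState:
    V: float
    m: float
    h: float

    def to_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h], dtype=float)


@dataclass
class StimulusProtocol:
    """A current-clamp protocol: one constant-current trace per stimulus.

    Defaults reproduce the experimental protocol: injections from -15 pA to
    35 pA in 5 pA steps, 50 ds (5 s) per step, sampled every 0.004 ds, i.e.
    N = 12500 samples per trace on the grid t_k = k * dt, k = 0..N-1.
    """

    currents: tuple[float, ...] = tuple(float(c) for c in range(-15, 40, 5))
    span: float = 50.0
    dt_out: float = 0.004

    @property
    def n_samples(self) -> int:
        return int(round(self.span / self.dt_out))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_out


def _gate_value(gate: GateSpec, state_V, state_m, state_h, params):
    if gate.kinetics == "dynamic":
        return state_m if gate.param_key == "m" else state_h
    return gate.equilibrium(state_V, params)


def total_membrane_current(V, m, h, params: ParameterVector, model: NeuronModel):
    """sum_ion I_ion at the given state, in pA."""
    total = 0.0
    for ch in model.channels:
        gates = [_gate_value(g, V, m, h, params) for g in ch.gates]
        exps = [g.exponent for g in ch.gates]
        total = total + channel_current(getattr(params, ch.conductance_key),
                                        getattr(params, ch.reversal_key),
                                        gates, exps, V)
    return total


def model_rhs(state, params: ParameterVector, model: NeuronModel, I: float):
    """Time derivatives (dV/dt, dm/dt, dh/dt) of the three-state CBM."""
    if params.C <= 0:
        raise InvalidParameterError("capacitance C must be positive")
    if params.tau_m <= 0 or params.tau_h <= 0:
        raise InvalidParameterError("gate time constants must be positive")
    if isinstance(state, ModelState):
        V, m, h = state.V, state.m, state.h
    else:
        V, m, h = state
    dV = (-total_membrane_current(V, m, h, params, model) + I) / params.C
    m_inf = boltzmann(V, params.V_half_m, params.k_m)
    h_inf = boltzmann(V, params.V_half_h, params.k_h)
    dm = (m_inf - m) / params.tau_m
    dh = (h_inf - h) / params.tau_h
    return np.array([dV, dm, dh], dtype=float)


# Reference solver settings: adaptive, stiff-capable, tight tolerances so that
# sampled traces are reproducible bit-for-bit for identical inputs.
_SOLVER_KW = dict(method="LSODA", rtol=1e-8, atol=1e-10)


def _integrate(params, model, I, y0, t_eval, span):
    def rhs(t, y):
        return model_rhs(y, params, model, I)

    sol = solve_ivp(rhs, (0.0, span), y0, t_eval=t_eval, **_SOLVER_KW)
    if not sol.success:
        raise IntegrationFailureError(
            f"integration failed for stimulus I={I} pA: {sol.message}")
    return sol.y


def simulate_current_clamp(model: NeuronModel, params: ParameterVector,
                           protocol: StimulusProtocol | None = None,
                           V0: float | None = None,
                           return_gates: bool = False):
    """Simulate the current-clamp protocol; one voltage trace per stimulus.

    Each trace starts independently from (V0, m0, h0) and is sampled on the
    uniform grid t_k = k * dt_out, k = 0..N-1.  Returns a dict mapping the
    stimulus (pA) to the sampled voltage array (and optionally gate arrays).
    """
    protocol = protocol or StimulusProtocol()
    params.validate()
    if V0 is None:
        V0 = -60.0
    t_eval = protocol.time_grid()
    traces = {}
    for I in protocol.currents:
        y = _integrate(params, model, I, [V0, params.m0, params.h0],
                       t_eval, protocol.span)
        traces[I] = (y[0], y[1], y[2]) if return_gates else y[0]
    return traces


def simulate_voltage_clamp(model: NeuronModel, params: ParameterVector,
                           V_H: float, duration: float = 20.0,
                           dt_out: float = 0.01,
                           m_init: float | None = None,
                           h_init: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a voltage-clamp step: V held at V_H, gates relax, the total
    membrane current is recorded.

    Returns (t, I_total).  Gates start from (m_init, h_init) if given, else
    from the parameter vector's (m0, h0).  With V fixed the gate equations are
    linear relaxations toward their Boltzmann equilibria, so the current tends
    to the analytic steady-state current as t -> infinity.
    """
    params.validate()
    m0 = params.m0 if m_init is None else m_init
    h0 = params.h0 if h_init is None else h_init

    def rhs(t, y):
        m, h = y
        dm = (boltzmann(V_H, params.V_half_m, params.k_m) - m) / params.tau_m
        dh = (boltzmann(V_H, params.V_half_h, params.k_h) - h) / params.tau_h
        return [dm, dh]

    t_eval = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (0.0, duration), [m0, h0], t_eval=t_eval, **_SOLVER_KW)
    if not sol.success:
        raise IntegrationFailureError(
            f"voltage-clamp integration failed at V_H={V_H} mV: {sol.message}")
    m, h = sol.y
    I_total = total_membrane_current(np.full_like(sol.t, V_H), m, h, params, model)
    return sol.t, np.asarray(I_total, dtype=float)
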