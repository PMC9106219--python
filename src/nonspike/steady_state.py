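"""Steady-state current analysis and bifurcation structure of non-spiking CBMs.

With every gate at its Boltzmann equilibrium the total membrane current
becomes a scalar function of voltage,

    I_inf(V) = sum_ion g_ion * m_inf^a(V) * h_inf^b(V) * (V - E_ion),

whose intersections with a horizontal line I = const are exactly the
equilibria of the full (V, m, h) system.  A monotonically increasing I_inf
yields a unique, globally attracting equilibrium for every injected current
(near-linear behaviour); an N-shaped I_inf yields a fold pair — as I is
ramped, a stable and an unstable equilibrium approach, coalesce and
annihilate in a saddle-node bifurcation — and bistable voltage jumps.

The derivative dI_inf/dV is computed analytically by chain rule through the
Boltzmann terms: d(x^a)/dV = a * x^a * (1 - x) / k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .model import (
    NeuronModel,
    ParameterVector,
    boltzmann,
    model_rhs,
)

__all__ = [
    "SteadyStateCurve",
    "Equilibrium",
    "BifurcationResult",
    "steady_state_current",
    "steady_state_derivative",
    "find_equilibria",
    "classify_stability",
    "saddle_node_currents",
    "classify_shape",
    "bifurcation_diagram",
    "scalar_slope_stability",
]

#: Default search window for equilibria, deliberately wider than the
#: [-100, 50] mV shape-classification window so folds just outside the data
#: range are still located.
DEFAULT_V_RANGE = (-120.0, 60.0)

#: Shape classification follows a fixed recipe: the derivative is evaluated on
#: 1501 uniform points of [-100, 50] mV, signs within +/- eps are discarded,
#: runs of identical sign are compressed and the run pattern is matched.
SHAPE_WINDOW = (-100.0, 50.0)
SHAPE_POINTS = 1501
SIGN_EPS = 1e-9

_ROOT_TOL = 1e-8          # bracketed root refinement tolerance, mV
_STAB_TOL = 1e-8          # eigenvalue real-part tolerance


@dataclass
class SteadyStateCurve:
    grid: np.ndarray           # mV, strictly increasing
    values: np.ndarray         # I_inf, pA
    derivative: np.ndarray     # dI_inf/dV, pA/mV


@dataclass
class Equilibrium:
    V_star: float
    stability: Literal["stable", "unstable", "marginal"]
    at_boundary: bool = False


@dataclass
class BifurcationResult:
    fold_currents: list[float]
    branches: list[tuple[float, float, str]]   # (I, V_star, stability)


def _channel_terms(params: ParameterVector, model: NeuronModel, V):
    """Yield (g, E, open_prob_product, slope_sum) per channel at equilibrium.

    ``slope_sum`` is sum_i a_i (1 - x_i) / k_i over the channel's gates, so the
    channel's dI/dV is g * prod * (slope_sum * (V - E) + 1).
    """
    V = np.asarray(V, dtype=float)
    for ch in model.channels:
        prod = np.ones_like(V)
        slope = np.zeros_like(V)
        for gate in ch.gates:
            V_half, k = params.gate_params(gate.param_key)
            x = boltzmann(V, V_half, k)
            prod = prod * x ** gate.exponent
            slope = slope + gate.exponent * (1.0 - x) / k
        yield (getattr(params, ch.conductance_key),
               getattr(params, ch.reversal_key), prod, slope)


def steady_state_current(params: ParameterVector, model: NeuronModel, V):
    """Analytic I_inf(V) in pA; independent of tau_m, tau_h, C, m0 and h0."""
    V = np.asarray(V, dtype=float)
    total = np.zeros_like(V)
    for g, E, prod, _ in _channel_terms(params, model, V):
        total = total + g * prod * (V - E)
    return total if total.ndim else float(total)


def steady_state_derivative(params: ParameterVector, model: NeuronModel, V):
    """Analytic dI_inf/dV in pA/mV (chain rule through each Boltzmann gate)."""
    V = np.asarray(V, dtype=float)
    total = np.zeros_like(V)
    for g, E, prod, slope in _channel_terms(params, model, V):
        total = total + g * prod * (slope * (V - E) + 1.0)
    return total if total.ndim else float(total)


def steady_state_curve(params, model, V_range=SHAPE_WINDOW,
                       n_points: int = SHAPE_POINTS) -> SteadyStateCurve:
    grid = np.linspace(V_range[0], V_range[1], n_points)
    return SteadyStateCurve(grid,
                            steady_state_current(params, model, grid),
                            steady_state_derivative(params, model, grid))


def _refine_brackets(f, grid, values):
    """Roots of f from sign changes of `values` on `grid`, brentq-refined."""
    roots = []
    sign = np.sign(values)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=_ROOT_TOL))
    # grid points that are themselves (numerically) exact roots
    for i in np.nonzero(values == 0.0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def _extrema_voltages(params, model, V_range, grid_points=14401):
    """Local extrema of I_inf: refined sign changes of its derivative."""
    grid = np.linspace(V_range[0], V_range[1], grid_points)
    deriv = steady_state_derivative(params, model, grid)
    f = lambda v: steady_state_derivative(params, model, v)
    return _refine_brackets(f, grid, deriv)


def find_equilibria(params: ParameterVector, model: NeuronModel, I: float,
                    V_range: tuple[float, float] = DEFAULT_V_RANGE,
                    grid_points: int = 14401) -> list[Equilibrium]:
    """All equilibria V* with I_inf(V*) = I inside V_range, sorted ascending.

    The window is partitioned at the local extrema of I_inf, so the curve is
    monotone on every segment and carries at most one root there, found by
    bracketed root-finding (robust even for near-tangent root pairs close to
    a fold); stability is attached from the full 3-state Jacobian.  A root
    within tolerance of the window edge is flagged ``at_boundary`` and a
    warning is issued.
    """
    f = lambda v: steady_state_current(params, model, v) - I
    cuts = [V_range[0]] + _extrema_voltages(params, model, V_range,
                                            grid_points) + [V_range[1]]
    roots = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        fa, fb = f(a), f(b)
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=_ROOT_TOL))
    if f(cuts[-1]) == 0.0:
        roots.append(cuts[-1])
    # merge numerically coincident roots (tangency at an extremum)
    roots = sorted(roots)
    roots = [r for i, r in enumerate(roots)
             if i == 0 or r - roots[i - 1] > 1e-7]
    out = []
    edge_tol = (V_range[1] - V_range[0]) * 1e-4
    for r in roots:
        at_edge = (r - V_range[0] < edge_tol) or (V_range[1] - r < edge_tol)
        if at_edge:
            warnings.warn(f"equilibrium at search-window boundary (V*={r:.3f} mV); "
                          "widen V_range", stacklevel=2)
        out.append(Equilibrium(r, classify_stability(params, model, r, I), at_edge))
    return out


def _jacobian(params: ParameterVector, model: NeuronModel, V, m, h, I):
    """Full 3-state Jacobian at (V, m, h) by central finite differences."""
    y0 = np.array([V, m, h], dtype=float)
    steps = np.array([1e-4, 1e-7, 1e-7])
    J = np.empty((3, 3))
    for j in range(3):
        yp, ym = y0.copy(), y0.copy()
        yp[j] += steps[j]
        ym[j] -= steps[j]
        J[:, j] = (model_rhs(yp, params, model, I)
                   - model_rhs(ym, params, model, I)) / (2 * steps[j])
    return J


def classify_stability(params: ParameterVector, model: NeuronModel,
                       V_star: float, I: float) -> str:
    """Linearize the full (V, m, h) system at the equilibrium.

    Stable iff all eigenvalue real parts < -tol, unstable iff any > +tol,
    otherwise marginal (tol = 1e-8).  This is authoritative; the scalar
    sign-of-slope criterion is exposed separately as a cross-check.
    """
    m_inf = boltzmann(V_star, params.V_half_m, params.k_m)
    h_inf = boltzmann(V_star, params.V_half_h, params.k_h)
    eig = np.linalg.eigvals(_jacobian(params, model, V_star, m_inf, h_inf, I))
    re = eig.real
    if np.all(re < -_STAB_TOL):
        return "stable"
    if np.any(re > _STAB_TOL):
        return "unstable"
    return "marginal"


def scalar_slope_stability(params, model, V_star) -> str:
    """Cross-check criterion: sign of dI_inf/dV at the equilibrium."""
    s = steady_state_derivative(params, model, V_star)
    if s > _STAB_TOL:
        return "stable"
    if s < -_STAB_TOL:
        return "unstable"
    return "marginal"


def saddle_node_currents(params: ParameterVector, model: NeuronModel,
                         V_range: tuple[float, float] = DEFAULT_V_RANGE,
                         grid_points: int = 14401) -> list[float]:
    """Injected currents at which saddle-node folds occur.

    Folds sit at local extrema of I_inf: sign changes of dI_inf/dV are
    bracketed on a dense grid, refined, and I_inf is evaluated there.  Sorted
    ascending; empty for monotonic curves.
    """
    extrema = _extrema_voltages(params, model, V_range, grid_points)
    return sorted(float(steady_state_current(params, model, v)) for v in extrema)


def classify_shape(params: ParameterVector, model: NeuronModel,
                   V_range: tuple[float, float] = SHAPE_WINDOW) -> str:
    """Classify the steady-state curve on the analysis window.

    ``monotonic``: dI_inf/dV > 0 throughout (near-linear neurons, RIM/AIY);
    ``n_shape``: sign pattern (+, -, +) (bistable neurons, AFD);
    anything else: ``other``.
    """
    grid = np.linspace(V_range[0], V_range[1], SHAPE_POINTS)
    deriv = steady_state_derivative(params, model, grid)
    signs = np.where(deriv > SIGN_EPS, 1, np.where(deriv < -SIGN_EPS, -1, 0))
    signs = signs[signs != 0]
    if signs.size == 0:
        return "other"
    pattern = [int(signs[0])]
    for s in signs[1:]:
        if s != pattern[-1]:
            pattern.append(int(s))
    if pattern == [1]:
        return "monotonic"
    if pattern == [1, -1, 1]:
        return "n_shape"
    return "other"


def bifurcation_diagram(params: ParameterVector, model: NeuronModel,
                        I_range: tuple[float, float], n_points: int = 201,
                        V_range: tuple[float, float] = DEFAULT_V_RANGE,
                        ) -> BifurcationResult:
    """Sweep the injected current and collect equilibria with stability."""
    folds = saddle_node_currents(params, model, V_range)
    branches = []
    for I in np.linspace(I_range[0], I_range[1], n_points):
        for eq in find_equilibria(params, model, I, V_range):
            branches.append((float(I), eq.V_star, eq.stability))
    return BifurcationResult(folds, branches)
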