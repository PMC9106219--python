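"""Vectorised trace simulation for population-based fitting.

Evaluating the voltage objective inside differential evolution requires
integrating every candidate parameterisation over every training stimulus,
thousands of times per run.  This module integrates the whole population in
one pass: states are (B, S) arrays (B candidates x S stimuli) advanced with a
splitting scheme that is unconditionally stable over the entire admissible
parameter box —

* gates are relaxed exactly toward their Boltzmann target over the step
  (the gate ODE is linear at frozen voltage), and
* the voltage is updated with an exponential (frozen-coefficient) step
  toward the instantaneous conductance-weighted reversal, using the exact
  solution of dV/dt = -(g_tot/C) (V - V_target).

The scheme is first-order accurate in the step; candidates whose parameters
make the membrane or the gates faster than the step simply snap to their
quasi-steady values instead of diverging, so no admissible genome produces a
numerical blow-up.  The reference adaptive solver in :mod:`nonspike.model`
remains the accurate path for single simulations; agreement between the two
is checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import _kernels
from .model import PARAM_NAMES, NeuronModel

__all__ = ["batch_simulate", "batch_f_V", "batch_f_inf", "BiObjective"]

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


def _structure(model: NeuronModel):
    """(g_pers, E_pers, g_trans, E_trans) genome column indices per class."""
    for ch in model.channels:
        for gate in ch.gates:
            if gate.exponent != 1:
                raise NotImplementedError(
                    "the vectorised path covers the canonical a=b=1 gate "
                    "exponents; use the reference simulator otherwise")
    if model.neuron_class in ("RIM", "AFD"):
        return _IDX["g_Ca"], _IDX["E_Ca"], _IDX["g_K"], _IDX["E_K"]
    if model.neuron_class == "AIY":
        return _IDX["g_K"], _IDX["E_K"], _IDX["g_Ca"], _IDX["E_Ca"]
    raise ValueError(f"unknown neuron class {model.neuron_class!r}")


def _columns(genomes, model):
    th = np.asarray(genomes, dtype=float)
    if th.ndim == 1:
        th = th[None, :]
    gp_i, ep_i, gt_i, et_i = _structure(model)
    c = lambda name: th[:, _IDX[name], None]
    return th, dict(
        g_pers=th[:, gp_i, None], E_pers=th[:, ep_i, None],
        g_trans=th[:, gt_i, None], E_trans=th[:, et_i, None],
        g_kir=c("g_Kir"), E_K=c("E_K"), g_L=c("g_L"), E_L=c("E_L"),
        Vh_p=c("V_half_p"), k_p=c("k_p"),
        Vh_kir=c("V_half_Kir"), k_kir=c("k_Kir"),
        Vh_m=c("V_half_m"), k_m=c("k_m"),
        Vh_h=c("V_half_h"), k_h=c("k_h"),
        tau_m=c("tau_m"), tau_h=c("tau_h"),
        C=c("C"), m0=c("m0"), h0=c("h0"),
    )


def batch_simulate(genomes, model: NeuronModel, currents, V0: float,
                   span: float, dt_out: float, n_sub: int = 1,
                   record: bool = True, data=None):
    """Integrate B genomes x S stimuli on the output grid t_k = k*dt_out.

    With ``record=True`` returns traces of shape (B, S, N).  With ``data``
    given (an (S, N) array of recorded voltages), returns instead the
    accumulated per-trace sum of squared residuals, shape (B, S), without
    storing trajectories.
    """
    th, p = _columns(genomes, model)
    B = th.shape[0]
    currents = np.asarray(currents, dtype=float)
    S = currents.size
    N = int(round(span / dt_out))
    dt = dt_out / n_sub

    I_ext = currents[None, :]
    V = np.full((B, S), float(V0))
    m = np.broadcast_to(p["m0"], (B, S)).copy()
    h = np.broadcast_to(p["h0"], (B, S)).copy()

    decay_m = np.exp(-dt / p["tau_m"])
    decay_h = np.exp(-dt / p["tau_h"])
    dt_over_C = dt / p["C"]

    if record:
        out = np.empty((B, S, N))
        out[:, :, 0] = V
    sse = None
    if data is not None:
        data = np.asarray(data, dtype=float)
        resid = V - data[None, :, 0]
        sse = resid * resid

    with np.errstate(under="ignore", over="ignore", invalid="ignore"):
        for k in range(1, N):
            for _ in range(n_sub):
                m_inf = expit((V - p["Vh_m"]) / p["k_m"])
                h_inf = expit((V - p["Vh_h"]) / p["k_h"])
                m = m_inf + (m - m_inf) * decay_m
                h = h_inf + (h - h_inf) * decay_h
                G_p = p["g_pers"] * expit((V - p["Vh_p"]) / p["k_p"])
                G_kir = p["g_kir"] * expit((V - p["Vh_kir"]) / p["k_kir"])
                G_t = p["g_trans"] * m * h
                g_tot = G_p + G_kir + G_t + p["g_L"] + 1e-12
                V_target = (G_p * p["E_pers"] + G_kir * p["E_K"]
                            + G_t * p["E_trans"] + p["g_L"] * p["E_L"]
                            + I_ext) / g_tot
                V = V_target + (V - V_target) * np.exp(-g_tot * dt_over_C)
            if record:
                out[:, :, k] = V
            if sse is not None:
                resid = V - data[None, :, k]
                sse += resid * resid

    if data is not None:
        return sse
    return out


def batch_f_V(genomes, model: NeuronModel, dataset, stimuli=None,
              n_sub: int = 1) -> np.ndarray:
    """Voltage objective for a batch of genomes, shape (B,).

    Same formula as :func:`nonspike.objectives.f_V` but computed with the
    exponential-Euler integrator (compiled kernel when numba is available,
    vectorised numpy otherwise).  Non-finite trajectories score +inf.
    """
    if stimuli is None:
        stimuli = dataset.stimuli
    stimuli = [float(s) for s in stimuli]
    proto = dataset.protocol
    data = np.stack([dataset.traces[s] for s in stimuli])
    sigma = np.array([dataset.sigma[s] for s in stimuli])
    th = np.atleast_2d(np.asarray(genomes, dtype=float))
    if _kernels.HAVE_NUMBA:
        gp_i, ep_i, gt_i, et_i = _structure(model)
        sse = _kernels.ee_sse(np.ascontiguousarray(th), gp_i, ep_i, gt_i, et_i,
                              np.asarray(stimuli, dtype=float), float(dataset.V0),
                              float(proto.dt_out), int(n_sub),
                              np.ascontiguousarray(data))
    else:
        sse = batch_simulate(th, model, stimuli, dataset.V0,
                             proto.span, proto.dt_out, n_sub=n_sub,
                             record=False, data=data)
    N = proto.n_samples
    scores = np.mean(np.sqrt(sse / N) / sigma[None, :], axis=1)
    return np.where(np.isfinite(scores), scores, np.inf)


def batch_f_inf(genomes, model: NeuronModel, dataset,
                variant: str = "per_point") -> np.ndarray:
    """Steady-state objective for a batch of genomes, shape (B,)."""
    th, p = _columns(genomes, model)
    V = np.asarray(dataset.V_H, dtype=float)[None, :]
    I_inf = (p["g_pers"] * expit((V - p["Vh_p"]) / p["k_p"]) * (V - p["E_pers"])
             + p["g_kir"] * expit((V - p["Vh_kir"]) / p["k_kir"]) * (V - p["E_K"])
             + p["g_trans"] * expit((V - p["Vh_m"]) / p["k_m"])
             * expit((V - p["Vh_h"]) / p["k_h"]) * (V - p["E_trans"])
             + p["g_L"] * (V - p["E_L"]))
    z = (np.asarray(dataset.mean_current)[None, :] - I_inf) / np.asarray(dataset.sigma)[None, :]
    if variant == "per_point":
        scores = np.mean(np.abs(z), axis=1)
    elif variant == "rmse":
        scores = np.sqrt(np.mean(z * z, axis=1))
    else:
        raise ValueError(f"unknown f_inf variant: {variant!r}")
    return np.where(np.isfinite(scores), scores, np.inf)


class BiObjective:
    """Batch evaluator of (f_V, f_inf) used by the fitting pipeline.

    ``stimuli`` restricts the voltage objective to the training traces;
    ``n_sub`` sets integration substeps per output sample.
    """

    def __init__(self, model, voltage_dataset, steady_state_dataset,
                 stimuli=None, n_sub: int = 1, f_inf_variant: str = "per_point"):
        self.model = model
        self.voltage_dataset = voltage_dataset
        self.steady_state_dataset = steady_state_dataset
        self.stimuli = list(stimuli) if stimuli is not None else None
        self.n_sub = n_sub
        self.f_inf_variant = f_inf_variant

    def primary(self, genomes) -> np.ndarray:
        return batch_f_V(genomes, self.model, self.voltage_dataset,
                         self.stimuli, self.n_sub)

    def secondary(self, genomes) -> np.ndarray:
        return batch_f_inf(genomes, self.model, self.steady_state_dataset,
                           self.f_inf_variant)

    def __call__(self, genomes) -> np.ndarray:
        return np.column_stack([self.primary(genomes), self.secondary(genomes)])
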