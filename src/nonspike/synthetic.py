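"""Ground-truth models and synthetic recordings for end-to-end validation.

Recorded voltage traces for the three neurons exist only as published
figures, so quantitative recovery experiments run on synthetic data: a
ground-truth parameterisation with a prescribed qualitative behaviour
(near-linear or bistable) is drawn, current-clamp traces are simulated and
corrupted with Gaussian noise, and cross-cell-averaged steady-state currents
are produced the way voltage-clamp experiments report them (averaging the
last 50 ms of each voltage step over a handful of cells).

The one real-data fixture is the published steady-state I-V table for the
RIM, AIY and AFD neurons (means across RIM: n=3, AIY: n=7, AFD: n=3 cells);
per-point standard deviations were not published, so a synthetic
sigma_VH = max(0.05 * |I_mean|, 0.5 pA) accompanies it by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SteadyStateDataset, VoltageDataset
from .model import (
    NeuronModel,
    ParameterVector,
    StimulusProtocol,
    boltzmann,
    build_model,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from .objectives import estimate_noise_level
from .steady_state import classify_shape, find_equilibria, saddle_node_currents

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "published_iv_table",
    "ground_truth_params",
    "reference_params",
    "generate_voltage_dataset",
    "generate_steady_state_dataset",
    "resting_state",
    "PUBLISHED_IV_MEANS",
]

# Published steady-state currents (pA) per holding voltage (mV); cells the
# experiment could not hold are absent.
PUBLISHED_IV_MEANS: dict[str, dict[float, float]] = {
    "RIM": {
        -100: -12.2, -90: -9.13, -80: -6.57, -70: -4.91, -60: -3.57,
        -50: -2.13, -40: -0.807, -30: 0.229, -20: 1.46, -10: 4.27,
        0: 7.46, 10: 11.8, 20: 17.2, 30: 21.6, 40: 27.1, 50: 32.5,
    },
    "AIY": {
        -120: -13.1, -110: -10.4, -100: -7.92, -90: -5.89, -80: -4.11,
        -70: -2.69, -60: -1.02, -50: 0.0211, -40: 1.17, -30: 3.1,
        -20: 7.32, -10: 14.2, 0: 22.4, 10: 31.5, 20: 43.2, 30: 54.5,
        40: 69.5, 50: 82.4,
    },
    "AFD": {
        -110: -68.6, -100: -49.5, -90: -18.2, -80: -5.06, -70: 2.19,
        -60: 3.37, -50: 2.52, -40: 2.68, -30: 5.97, -20: 14.6, -10: 33.4,
        0: 60.2, 10: 85.0, 20: 114.0, 30: 152.0, 40: 208.0, 50: 254.0,
    },
}

_N_CELLS = {"RIM": 3, "AIY": 7, "AFD": 3}


def published_iv_table(neuron_class: str, sigma_rel: float = 0.05,
                       sigma_floor: float = 0.5) -> SteadyStateDataset:
    """The packaged experimental steady-state I-V table for one neuron.

    Only means were published; sigma is synthesised as
    max(sigma_rel * |I_mean|, sigma_floor).
    """
    try:
        column = PUBLISHED_IV_MEANS[neuron_class]
    except KeyError:
        raise ValueError(f"unknown neuron class: {neuron_class!r}") from None
    V = np.array(sorted(column), dtype=float)
    I = np.array([column[v] for v in V])
    sigma = np.maximum(sigma_rel * np.abs(I), sigma_floor)
    return SteadyStateDataset(V, I, sigma, n_cells=_N_CELLS[neuron_class])


@dataclass
class NoiseSpec:
    """Measurement-noise model for synthetic recordings.

    ``voltage_sd``: per-sample Gaussian noise on current-clamp traces (mV);
    ``current_sd``: per-cell Gaussian noise on clamp steady-state currents
    (pA); ``n_cells``: pseudo-cells averaged per steady-state point.
    """

    voltage_sd: float = 0.5
    current_sd: float = 5.0
    n_cells: int = 3

    def __post_init__(self):
        if self.voltage_sd < 0 or self.current_sd < 0 or self.n_cells < 1:
            raise ValueError("noise levels must be >= 0 and n_cells >= 1")


@dataclass
class GroundTruth:
    params: ParameterVector
    neuron_class: str
    behavior: str               # near_linear | bistable
    seed: int
    resting_potential: float


def resting_state(params: ParameterVector, model: NeuronModel) -> float:
    """Resting potential: the most hyperpolarised stable equilibrium at I=0."""
    eqs = [e for e in find_equilibria(params, model, 0.0) if e.stability == "stable"]
    if not eqs:
        raise ValueError("model has no stable equilibrium at I = 0")
    return eqs[0].V_star


# Physiological sampling box for ground-truth draws, by functional role.
# Conductances of a few nS, reversal potentials near their ionic values and
# gate midpoints in the subthreshold range keep the simulated deflections on
# the few-to-tens-of-mV scale of the recordings.
_SAMPLING_RANGES = {
    "g_pers": (0.2, 2.5), "g_trans": (0.5, 3.0),
    "g_Kir": (0.1, 2.0), "g_L": (0.05, 0.8),
    "E_Ca": (60.0, 130.0), "E_K": (-95.0, -60.0), "E_L": (-75.0, -40.0),
    "V_half_p": (-55.0, -10.0), "k_p": (4.0, 15.0),
    "V_half_Kir": (-80.0, -40.0), "k_Kir": (-20.0, -6.0),
    "V_half_m": (-55.0, -10.0), "k_m": (4.0, 15.0),
    "V_half_h": (-65.0, -25.0), "k_h": (-15.0, -4.0),
    "tau_m": (0.2, 3.0), "tau_h": (0.5, 5.0),
    "C": (0.5, 3.0),
}


def _draw_params(neuron_class: str, rng: np.random.Generator) -> ParameterVector:
    u = {k: rng.uniform(*v) for k, v in _SAMPLING_RANGES.items()}
    if neuron_class in ("RIM", "AFD"):
        g_Ca, g_K = u["g_pers"], u["g_trans"]
    else:
        g_Ca, g_K = u["g_trans"], u["g_pers"]
    return ParameterVector(
        g_Ca=g_Ca, g_Kir=u["g_Kir"], g_K=g_K, g_L=u["g_L"],
        E_Ca=u["E_Ca"], E_K=u["E_K"], E_L=u["E_L"],
        V_half_p=u["V_half_p"], k_p=u["k_p"],
        V_half_Kir=u["V_half_Kir"], k_Kir=u["k_Kir"],
        V_half_m=u["V_half_m"], k_m=u["k_m"],
        V_half_h=u["V_half_h"], k_h=u["k_h"],
        tau_m=u["tau_m"], tau_h=u["tau_h"], C=u["C"],
        m0=0.5, h0=0.5,
    )


def _acceptable(params, model, behavior):
    shape = classify_shape(params, model)
    if behavior == "near_linear":
        if shape != "monotonic":
            return None
        rest_window = (-90.0, -20.0)
    elif behavior == "bistable":
        if shape != "n_shape":
            return None
        folds = saddle_node_currents(params, model)
        # the depolarising jump must fall inside the stimulus range
        if len(folds) < 2 or not (0.0 < max(folds) < 30.0):
            return None
        rest_window = (-90.0, -30.0)
    else:
        raise ValueError(f"unknown behavior: {behavior!r}")
    try:
        rest = resting_state(params, model)
    except ValueError:
        return None
    if not (rest_window[0] <= rest <= rest_window[1]):
        return None
    return rest


def ground_truth_params(neuron_class: str, behavior: str, seed: int,
                        max_draws: int = 5000) -> GroundTruth:
    """Draw an in-bounds ground-truth parameterisation with the requested
    qualitative behaviour, by rejection sampling; deterministic per seed.

    Initial gate states are pinned to their Boltzmann equilibria at the
    resting potential, so simulated protocols start from rest.
    """
    model = build_model(neuron_class)
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        params = _draw_params(neuron_class, rng)
        rest = _acceptable(params, model, behavior)
        if rest is None:
            continue
        params = params.replace(
            m0=float(boltzmann(rest, params.V_half_m, params.k_m)),
            h0=float(boltzmann(rest, params.V_half_h, params.k_h)))
        return GroundTruth(params, neuron_class, behavior, seed, rest)
    raise RuntimeError(
        f"rejection budget ({max_draws} draws) exhausted for "
        f"{neuron_class}/{behavior} ground truth (seed {seed})")


def reference_params(behavior: str) -> GroundTruth:
    """Fixed, documented reference ground truths used across the test suite.

    Deterministic wrappers over :func:`ground_truth_params` with frozen seeds:
    ``near_linear`` is a RIM-class model with a monotonic steady-state curve,
    ``bistable`` an AFD-class model whose N-shaped curve folds inside the
    stimulated current range.
    """
    if behavior == "near_linear":
        return ground_truth_params("RIM", "near_linear", seed=20)
    if behavior == "bistable":
        return ground_truth_params("AFD", "bistable", seed=21)
    raise ValueError(f"unknown behavior: {behavior!r}")


def generate_voltage_dataset(truth: GroundTruth,
                             protocol: StimulusProtocol | None = None,
                             noise: NoiseSpec | None = None,
                             seed: int = 0) -> VoltageDataset:
    """Noisy current-clamp traces from a ground-truth model.

    Each stimulus is simulated from rest (V0 = resting potential, gates at
    equilibrium), iid Gaussian noise of sd ``voltage_sd`` is added to every
    sample, and the per-trace noise level sigma_I is re-estimated from the
    flat tail of the noisy trace — the same procedure applied to recordings.
    """
    protocol = protocol or StimulusProtocol()
    noise = noise or NoiseSpec()
    model = build_model(truth.neuron_class)
    rng = np.random.default_rng(seed)
    clean = simulate_current_clamp(model, truth.params, protocol,
                                   V0=truth.resting_potential)
    traces, sigma = {}, {}
    for I in protocol.currents:
        tr = clean[I] + rng.normal(0.0, noise.voltage_sd, size=len(clean[I])) \
            if noise.voltage_sd > 0 else clean[I].copy()
        traces[I] = tr
        sigma[I] = max(estimate_noise_level(tr), 1e-9)
    return VoltageDataset(protocol, traces, sigma, truth.resting_potential)


def generate_steady_state_dataset(truth: GroundTruth, V_grid=None,
                                  noise: NoiseSpec | None = None,
                                  seed: int = 0,
                                  duration: float | None = None,
                                  sigma_floor: float = 0.5,
                                  sigma_rel_floor: float = 0.05) -> SteadyStateDataset:
    """Cross-cell-averaged steady-state currents from voltage-clamp steps.

    For each holding voltage the clamp is simulated from rest-equilibrium
    gates, the current over the last 0.5 ds (50 ms) of the step is averaged,
    and each pseudo-cell observes that value plus Gaussian noise of sd
    ``current_sd``; the dataset stores the across-cell mean and standard
    deviation.  With only a handful of cells the sample sd is itself noisy,
    so it is floored both absolutely (``sigma_floor``, the measurement
    resolution) and relative to the signal (``sigma_rel_floor`` * |mean|,
    gain uncertainty) — the same convention the packaged experimental table
    uses for its synthesised sigma.
    """
    noise = noise or NoiseSpec()
    model = build_model(truth.neuron_class)
    rng = np.random.default_rng(seed)
    if V_grid is None:
        V_grid = np.arange(-100.0, 51.0, 10.0)
    V_grid = np.asarray(V_grid, dtype=float)
    p = truth.params
    if duration is None:
        duration = 16.0 * max(p.tau_m, p.tau_h) + 1.0
    m_rest = float(boltzmann(truth.resting_potential, p.V_half_m, p.k_m))
    h_rest = float(boltzmann(truth.resting_potential, p.V_half_h, p.k_h))
    means, sds = [], []
    for V_H in V_grid:
        t, I_tr = simulate_voltage_clamp(model, p, V_H, duration=duration,
                                         m_init=m_rest, h_init=h_rest)
        tail = t >= duration - 0.5
        I_ss = float(np.mean(I_tr[tail]))
        cells = I_ss + (rng.normal(0.0, noise.current_sd, size=noise.n_cells)
                        if noise.current_sd > 0 else np.zeros(noise.n_cells))
        means.append(float(np.mean(cells)))
        sds.append(float(np.std(cells, ddof=1)) if noise.n_cells > 1 else 0.0)
    means = np.asarray(means)
    sigma = np.maximum.reduce([np.asarray(sds), sigma_rel_floor * np.abs(means),
                               np.full_like(means, sigma_floor)])
    return SteadyStateDataset(V_grid, means, sigma, n_cells=noise.n_cells)
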