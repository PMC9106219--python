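"""Cost functions for fitting non-spiking CBMs.

Primary objective — voltage traces.  For each injected current I the model is
simulated from (V0, m0, h0) on the dataset's grid and the per-trace RMSE,
normalised to that trace's experimental noise level sigma_I, is averaged over
stimuli:

    f_V(theta_V) = (1/|I|) * sum_I  sqrt((1/N) sum_t (V_exp - V_model)^2) / sigma_I

sigma_I is estimated from a time window at the end of each trace where the
curve is relatively flat (sample standard deviation).

Secondary objective — steady-state current.  The analytic steady-state curve
is compared against the cross-cell experimental means at each holding
voltage, each deviation normalised to the per-point standard deviation and
averaged over the grid:

    f_inf(theta_SS) = (1/|V_H|) * sum_VH  |I_exp(V_H) - I_inf(V_H)| / sigma_VH

This is the per-point normalised reading of the formula; a single
grid-wide RMSE variant is available via ``variant="rmse"``.  f_inf depends
only on the steady-state-relevant parameter subset theta_SS (it is exactly
invariant to tau_m, tau_h, C, m0 and h0).

Failed trace integrations score +inf so optimisers discard the candidate.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datasets import SteadyStateDataset, VoltageDataset
from .model import (
    IntegrationFailureError,
    NeuronModel,
    ParameterVector,
    simulate_current_clamp,
)
from .steady_state import steady_state_current

__all__ = ["estimate_noise_level", "f_V", "f_inf", "DEFAULT_NOISE_WINDOW_FRACTION"]

logger = logging.getLogger(__name__)

#: Fraction of the trace tail used for noise-level estimation (last 10%,
#: i.e. 1250 samples at the default 12500-sample protocol).
DEFAULT_NOISE_WINDOW_FRACTION = 0.10


def estimate_noise_level(trace, window: tuple[int, int] | None = None) -> float:
    """Sample standard deviation of a trace over an index window.

    ``window`` is a half-open index interval (start, stop); by default the
    final 10% of the trace.  The window must contain at least two samples.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if window is None:
        window = (n - max(2, int(round(DEFAULT_NOISE_WINDOW_FRACTION * n))), n)
    start, stop = window
    if start < 0 or stop > n or stop <= start:
        raise ValueError(f"window {window} outside trace of length {n}")
    if stop - start < 2:
        raise ValueError("noise window must contain at least 2 samples")
    return float(np.std(trace[start:stop], ddof=1))


def f_V(params: ParameterVector, model: NeuronModel,
        dataset: VoltageDataset, stimuli=None) -> float:
    """Noise-normalised RMSE of simulated vs recorded voltage traces.

    Optionally restricted to a subset of stimuli (e.g. the validation trace
    alone, in which case |I| = 1).  Returns +inf when any trace integration
    fails.
    """
    if stimuli is None:
        stimuli = dataset.stimuli
    stimuli = [float(s) for s in stimuli]
    proto = dataset.protocol
    from .model import StimulusProtocol
    run_proto = StimulusProtocol(tuple(stimuli), proto.span, proto.dt_out)
    try:
        sim = simulate_current_clamp(model, params, run_proto, V0=dataset.V0)
    except IntegrationFailureError as exc:
        logger.warning("f_V: integration failure, scoring +inf (%s)", exc)
        return math.inf
    total = 0.0
    for I in stimuli:
        resid = dataset.traces[I] - sim[I]
        rmse = math.sqrt(float(np.mean(resid * resid)))
        total += rmse / dataset.sigma[I]
    return total / len(stimuli)


def f_inf(params: ParameterVector, model: NeuronModel,
          dataset: SteadyStateDataset, variant: str = "per_point") -> float:
    """Noise-normalised deviation of the analytic steady-state curve.

    ``variant="per_point"`` (default): mean over the V_H grid of
    |I_exp - I_inf| / sigma_VH.  ``variant="rmse"``: a single RMSE of the
    normalised deviations over the grid.
    """
    pred = steady_state_current(params, model, dataset.V_H)
    z = (dataset.mean_current - pred) / dataset.sigma
    if variant == "per_point":
        return float(np.mean(np.abs(z)))
    if variant == "rmse":
        return float(np.sqrt(np.mean(z * z)))
    raise ValueError(f"unknown f_inf variant: {variant!r}")
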