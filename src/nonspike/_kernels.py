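"""Compiled scoring kernel for the exponential-Euler trace evaluator.

The inner integration loop of :func:`nonspike.fastsim.batch_f_V` is the hot
path of every fitting run; this module provides a numba-compiled version that
makes single-candidate evaluation cheap enough for immediate (per-candidate)
selection inside DEMO.  A pure-numpy fallback in :mod:`nonspike.fastsim` is
used when numba is unavailable; both paths implement the identical scheme and
are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@njit(cache=False)
def _sigmoid(z):
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=False)
def ee_sse(th, gp_i, ep_i, gt_i, et_i, currents, V0, dt_out, n_sub, data):
    """Sum of squared residuals per (candidate, stimulus).

    ``th``: (B, 20) genomes in the canonical layout; ``data``: (S, N)
    recorded traces sampled at t_k = k*dt_out; the integration uses ``n_sub``
    exponential-Euler substeps per sample.  Layout indices of the persistent
    and transient conductances/reversals are passed explicitly so the kernel
    serves both model classes.
    """
    B = th.shape[0]
    S = currents.shape[0]
    N = data.shape[1]
    dt = dt_out / n_sub
    sse = np.zeros((B, S))
    for b in range(B):
        g_pers = th[b, gp_i]
        E_pers = th[b, ep_i]
        g_trans = th[b, gt_i]
        E_trans = th[b, et_i]
        g_kir = th[b, 1]
        g_L = th[b, 3]
        E_K = th[b, 5]
        E_L = th[b, 6]
        Vh_p = th[b, 7]
        k_p = th[b, 8]
        Vh_kir = th[b, 9]
        k_kir = th[b, 10]
        Vh_m = th[b, 11]
        k_m = th[b, 12]
        Vh_h = th[b, 13]
        k_h = th[b, 14]
        tau_m = th[b, 15]
        tau_h = th[b, 16]
        C = th[b, 17]
        m_init = th[b, 18]
        h_init = th[b, 19]
        decay_m = np.exp(-dt / tau_m)
        decay_h = np.exp(-dt / tau_h)
        for s in range(S):
            I_ext = currents[s]
            V = V0
            m = m_init
            h = h_init
            r = V - data[s, 0]
            acc = r * r
            for k in range(1, N):
                for _ in range(n_sub):
                    m_inf = _sigmoid((V - Vh_m) / k_m)
                    h_inf = _sigmoid((V - Vh_h) / k_h)
                    m = m_inf + (m - m_inf) * decay_m
                    h = h_inf + (h - h_inf) * decay_h
                    G_p = g_pers * _sigmoid((V - Vh_p) / k_p)
                    G_kir = g_kir * _sigmoid((V - Vh_kir) / k_kir)
                    G_t = g_trans * m * h
                    g_tot = G_p + G_kir + G_t + g_L + 1e-12
                    V_target = (G_p * E_pers + G_kir * E_K + G_t * E_trans
                                + g_L * E_L + I_ext) / g_tot
                    V = V_target + (V - V_target) * np.exp(-g_tot * dt / C)
                r = V - data[s, k]
                acc += r * r
            sse[b, s] = acc
    return sse
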