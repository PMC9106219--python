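"""Shared fixtures: models, reference ground truths and small datasets.

Everything is generated programmatically; the reference ground truths are the
package's documented frozen fixtures (one near-linear, one bistable) and the
short protocol (span 10 ds, dt 0.04 ds) keeps simulation-heavy tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import nonspike as ns


@pytest.fixture(scope="session")
def rim_model():
    return ns.build_model("RIM")


@pytest.fixture(scope="session")
def afd_model():
    return ns.build_model("AFD")


@pytest.fixture(scope="session")
def aiy_model():
    return ns.build_model("AIY")


@pytest.fixture(scope="session")
def bounds():
    return ns.default_bounds()


@pytest.fixture(scope="session")
def near_linear_truth():
    return ns.reference_params("near_linear")


@pytest.fixture(scope="session")
def bistable_truth():
    return ns.reference_params("bistable")


@pytest.fixture(scope="session")
def short_protocol():
    return ns.StimulusProtocol(span=10.0, dt_out=0.04)


@pytest.fixture(scope="session")
def leak_only():
    """A pure-RC parameterisation: all gated conductances off."""
    return ns.ParameterVector(g_Ca=0.0, g_Kir=0.0, g_K=0.0, g_L=0.5,
                              E_L=-60.0, C=1.0, tau_m=1.0, tau_h=1.0)


@pytest.fixture(scope="session")
def near_linear_dataset(near_linear_truth, short_protocol):
    vd = ns.generate_voltage_dataset(near_linear_truth, short_protocol,
                                     ns.NoiseSpec(), seed=1000)
    sd = ns.generate_steady_state_dataset(near_linear_truth,
                                          noise=ns.NoiseSpec(), seed=2000)
    return vd, sd


def sample_valid_params(bounds, rng, n):
    """Random in-bounds parameter vectors that satisfy structural validity."""
    out = []
    while len(out) < n:
        g = bounds.sample(rng, 1)[0]
        p = ns.ParameterVector.from_array(g)
        try:
            p.validate()
        except ns.InvalidParameterError:
            continue
        out.append(p)
    return out
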