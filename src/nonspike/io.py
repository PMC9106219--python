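"""Serialisation of parameter sets and optimisation artifacts.

Parameter sets are JSON objects carrying the neuron class, the unit
declaration and a name -> value map; populations and Pareto sets are CSV
tables with one genome column per parameter plus the two objective columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, ParameterVector
from .optimize import Individual, ParetoSet

__all__ = ["save_params", "load_params", "save_population", "load_population"]

UNITS = {"voltage": "mV", "current": "pA", "conductance": "nS",
         "time": "ds", "capacitance": "pA*ds/mV"}


def save_params(params: ParameterVector, neuron_class: str, path) -> None:
    Path(path).write_text(json.dumps({
        "neuron_class": neuron_class,
        "units": UNITS,
        "parameters": params.to_dict(),
    }, indent=2))


def load_params(path) -> tuple[ParameterVector, str]:
    data = json.loads(Path(path).read_text())
    return ParameterVector.from_dict(data["parameters"]), data["neuron_class"]


def save_population(individuals, path) -> None:
    """Population snapshot: genome columns + f_V + f_inf."""
    rows = []
    for ind in individuals:
        row = {n: v for n, v in zip(PARAM_NAMES, ind.genome)}
        obj = ind.objectives
        if obj is not None and np.ndim(obj) > 0:
            row["f_V"], row["f_inf"] = obj
        elif obj is not None:
            row["f_V"] = obj
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_population(path) -> list[Individual]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        genome = row[list(PARAM_NAMES)].to_numpy(dtype=float)
        if "f_inf" in row:
            obj = (float(row["f_V"]), float(row["f_inf"]))
        elif "f_V" in row:
            obj = float(row["f_V"])
        else:
            obj = None
        out.append(Individual(genome, obj))
    return out
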