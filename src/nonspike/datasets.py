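"""Dataset containers for current-clamp traces and steady-state I-V tables.

A :class:`VoltageDataset` holds one sampled voltage trace per injected
current, all on a shared time grid, plus the per-trace noise level sigma_I
used to normalise the voltage cost function, and the common initial potential
V0.  A :class:`SteadyStateDataset` holds the voltage-clamp grid V_H, the
cross-cell mean steady-state currents and their standard deviations.

On disk, traces travel as long-format CSV (stimulus_pA, time_ds, voltage_mV)
with a sidecar JSON carrying sigma_I per stimulus and V0; steady-state tables
as CSV (V_mV, I_mean_pA, I_sd_pA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import StimulusProtocol

__all__ = ["VoltageDataset", "SteadyStateDataset"]


@dataclass
class VoltageDataset:
    protocol: StimulusProtocol
    traces: dict[float, np.ndarray]      # stimulus (pA) -> voltage (mV), length N
    sigma: dict[float, float]            # stimulus (pA) -> noise level (mV)
    V0: float                            # shared initial potential (mV)

    def __post_init__(self):
        n = self.protocol.n_samples
        for I, tr in self.traces.items():
            if len(tr) != n:
                raise ValueError(
                    f"trace at {I} pA has {len(tr)} samples, expected {n}")
        for I in self.traces:
            if I not in self.sigma:
                raise ValueError(f"missing sigma for stimulus {I} pA")
            if self.sigma[I] <= 0:
                raise ValueError(f"sigma must be > 0 (stimulus {I} pA)")

    @property
    def stimuli(self) -> tuple[float, ...]:
        return tuple(self.traces)

    def subset(self, stimuli) -> "VoltageDataset":
        stimuli = [float(s) for s in stimuli]
        missing = [s for s in stimuli if s not in self.traces]
        if missing:
            raise KeyError(f"stimuli not in dataset: {missing}")
        proto = StimulusProtocol(tuple(stimuli), self.protocol.span,
                                 self.protocol.dt_out)
        return VoltageDataset(proto,
                              {s: self.traces[s] for s in stimuli},
                              {s: self.sigma[s] for s in stimuli},
                              self.V0)

    # ---- disk round trip -------------------------------------------------

    def to_csv(self, csv_path, sidecar_path=None) -> None:
        csv_path = Path(csv_path)
        frames = []
        t = self.protocol.time_grid()
        for I, tr in self.traces.items():
            frames.append(pd.DataFrame(
                {"stimulus_pA": I, "time_ds": t, "voltage_mV": tr}))
        pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "V0_mV": self.V0,
            "span_ds": self.protocol.span,
            "dt_out_ds": self.protocol.dt_out,
            "sigma_mV": {str(I): s for I, s in self.sigma.items()},
        }, indent=2))

    @classmethod
    def from_csv(cls, csv_path, sidecar_path=None) -> "VoltageDataset":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        traces = {}
        for I, grp in df.groupby("stimulus_pA"):
            traces[float(I)] = grp.sort_values("time_ds")["voltage_mV"].to_numpy()
        proto = StimulusProtocol(tuple(traces), float(meta["span_ds"]),
                                 float(meta["dt_out_ds"]))
        sigma = {float(k): float(v) for k, v in meta["sigma_mV"].items()}
        return cls(proto, traces, sigma, float(meta["V0_mV"]))


@dataclass
class SteadyStateDataset:
    V_H: np.ndarray            # holding voltages (mV), ordered
    mean_current: np.ndarray   # pA
    sigma: np.ndarray          # pA, > 0
    n_cells: int = 1

    def __post_init__(self):
        self.V_H = np.asarray(self.V_H, dtype=float)
        self.mean_current = np.asarray(self.mean_current, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.V_H) == len(self.mean_current) == len(self.sigma)):
            raise ValueError("V_H, mean_current and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma_VH must be > 0")

    def __len__(self) -> int:
        return len(self.V_H)

    def to_csv(self, path) -> None:
        pd.DataFrame({"V_mV": self.V_H, "I_mean_pA": self.mean_current,
                      "I_sd_pA": self.sigma}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_cells: int = 1) -> "SteadyStateDataset":
        df = pd.read_csv(path)
        return cls(df["V_mV"].to_numpy(), df["I_mean_pA"].to_numpy(),
                   df["I_sd_pA"].to_numpy(), n_cells)
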