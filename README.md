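# nonspike

Conductance-based modelling of **non-spiking (graded-potential) neurons**:
protocol simulation, steady-state/bifurcation analysis, bi-objective
evolutionary fitting, and automated model selection with generalization in
mind. The package targets the three electrophysiologically characterised
non-spiking neuron classes of *C. elegans* — RIM and AIY (near-linear graded
responses) and AFD (bistable, with voltage jumps) — but the machinery
applies to any cell whose behaviour fits the supported channel compositions.

## The problem

A conductance-based model (CBM)

    C dV/dt = −Σ_ion g_ion m^a h^b (V − E_ion) + I,
    dx/dt = (x_∞(V) − x)/τ_x,   x_∞(V) = 1/(1 + exp((V_half − V)/k)),

has ~20 free parameters even for a small non-spiking cell, and a parameter
set that reproduces a family of current-clamp traces can still respond
absurdly to the *next* stimulus. What disciplines the fit is the
**steady-state current** I_∞(V) — the total membrane current with every gate
at equilibrium — because its intersections with I = const are exactly the
equilibria of the system: a monotonic I_∞ means one globally attracting
equilibrium per stimulus (near-linear behaviour), while an N-shaped I_∞
carries a saddle-node fold pair and bistable jumps. `nonspike` therefore
fits two objectives at once,

* **f_V** — per-trace RMSE of simulated vs recorded voltages, normalised to
  each trace's noise level, averaged over stimuli;
* **f_∞** — deviation of the analytic I_∞ from the cross-cell mean
  steady-state currents, normalised per point to their standard deviation;

using a biased multi-objective differential evolution
(**DEMO/rand/best/biased**: a preliminary single-objective DE seeds each
run, and mutation anchors to the best primary-objective individual), and
then selects one model by a four-step process: split the data
(train −15..25 pA + I-V table / validate 30 pA / test 35 pA), pool the runs'
final populations and keep the non-dominated set, discard candidates whose
I_∞ shape does not match the cell class, and pick the member with the lowest
validation-trace cost. The test trace is never consulted by selection.

## Worked example

Analyse the packaged bistable (AFD-class) reference model and score it
against its own synthetic recordings:

```python
import nonspike as ns

truth = ns.reference_params("bistable")      # frozen AFD-class ground truth
model = ns.build_model("AFD")
p = truth.params

print("shape:", ns.classify_shape(p, model))
print("folds:", [round(c, 2) for c in ns.saddle_node_currents(p, model)])
print("equilibria at I=0:",
      [(round(e.V_star, 2), e.stability) for e in ns.find_equilibria(p, model, 0.0)])

proto = ns.StimulusProtocol(span=10, dt_out=0.04)        # shortened protocol
vd = ns.generate_voltage_dataset(truth, proto, ns.NoiseSpec(), seed=1)
sd = ns.generate_steady_state_dataset(truth, noise=ns.NoiseSpec(), seed=2)
train = vd.subset([float(c) for c in range(-15, 30, 5)])
print("f_V(truth):", round(ns.f_V(p, model, train), 3))
print("f_inf(truth):", round(ns.f_inf(p, model, sd), 3))
```

prints

```
shape: n_shape
folds: [-28.13, 10.46]
equilibria at I=0: [(-79.77, 'stable'), (-46.31, 'unstable'), (32.02, 'stable')]
f_V(truth): 0.907
f_inf(truth): 1.014
```

The N-shaped steady-state curve folds at I ≈ −28.1 and ≈ 10.5 pA: ramping
the injected current past ~10.5 pA annihilates the resting state at
−79.8 mV and the voltage jumps to the depolarised branch near +32 mV —
the bistable signature. Both costs sit near 1, i.e. the true parameters fit
their own noisy data to within the noise level, which is the calibration a
correctly normalised cost should show.

To fit models to data end to end:

```python
cfg = ns.scaled_config("AFD", seed=0)        # NP=60, 300 generations, 3 runs
report = ns.run_pipeline(vd, sd, cfg)
print(report.S_size, report.S1_size, report.validation_score)
```

or from a shell, via the `nonspike` CLI (`simulate`, `steady-state`,
`bifurcate`, `synth`, `fit`/`decide` subcommands):

```bash
nonspike synth --neuron AFD --behavior bistable --seed 3 --out data/
nonspike decide --neuron AFD --traces data/traces.csv --iv data/iv.csv --out run/
```

The experimental steady-state I-V table for RIM, AIY and AFD ships with the
package (`ns.published_iv_table("AFD")`); voltage recordings are emulated by the
synthetic generator, since the published traces exist only as figures.

## Layout

| module | contents |
| --- | --- |
| `nonspike.model` | channel/gate specifications, parameter vector, reference ODE simulation of current- and voltage-clamp protocols |
| `nonspike.steady_state` | analytic I_∞ and derivative, equilibria, stability, saddle-node folds, shape classification, bifurcation diagrams |
| `nonspike.objectives` / `nonspike.datasets` | the two cost functions, noise estimation, dataset containers and CSV/JSON round trips |
| `nonspike.fastsim` / `nonspike._kernels` | population-scale exponential-Euler trace evaluation (numba kernel + numpy fallback) |
| `nonspike.optimize` | bound-constrained DE, DEMO/rand/best/biased, non-dominated sorting, crowding truncation |
| `nonspike.pipeline` | the four-step selection process and its report |
| `nonspike.synthetic` | ground-truth sampling, noisy recording emulation, the packaged I-V table |
| `nonspike.cli` | `nonspike` command-line interface |

See `docs/methods.md` for the model equations, numerical choices, the
synthetic-data assumptions and known limitations.
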