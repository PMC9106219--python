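# Methods

`nonspike` builds conductance-based models (CBMs) of non-spiking neurons from
two kinds of macroscopic recordings — current-clamp voltage traces and
voltage-clamp steady-state currents — and selects, among the candidates a
bi-objective evolutionary search produces, one model whose bifurcation
structure matches the neuron's qualitative behaviour. This note records the
model, the numerical choices, the synthetic-data assumptions and the design
decisions a maintainer would want to know.

## Model

The membrane potential obeys

    C dV/dt = -Σ_ion I_ion + I,     I_ion = g_ion m^a h^b (V - E_ion),

with activation/inactivation gates relaxing to Boltzmann equilibria

    dx/dt = (x_inf(V) - x)/τ_x,     x_inf(V) = 1/(1 + exp((V_half^x - V)/k_x)),

where k > 0 denotes activation and k < 0 inactivation. Two channel
compositions are supported, one per observed response class of the three
*C. elegans* neurons they model:

* RIM / AFD: persistent calcium + inward-rectifier potassium + transient
  potassium + leak (I_Ca,p + I_Kir + I_K,t + I_L);
* AIY: transient calcium + inward rectifier + persistent potassium + leak
  (I_Ca,t + I_Kir + I_K,p + I_L).

Only the transient channel's activation m and inactivation h are dynamic;
the persistent and Kir activations are instantaneous Boltzmann functions of
the voltage evaluated inside the right-hand side, so the state is (V, m, h).
Gate exponents default to a = b = 1 but are configurable fields of the
channel specification. The Kir conductance is a single "activation-form"
gate with negative slope (k_Kir < 0): it opens under hyperpolarisation.

**Units.** mV, pA, nS and deciseconds (1 ds = 100 ms; a 5 s stimulus step is
50 ds). Capacitance is carried in the consistent derived unit pA·ds/mV
(= nS·ds), which makes the membrane equation dimensionless-clean without
conversion factors; the admissible interval (0, 10] is interpreted in these
units.

**Parameterisation.** A model instance has 20 free parameters: four maximal
conductances, three reversal potentials, four (V_half, k) pairs (persistent
activation, Kir activation, transient activation m, transient inactivation
h), two time constants, the capacitance and the two initial gate states
m0, h0. The steady-state-relevant subset θ_SS (15 parameters) excludes
τ_m, τ_h, C, m0, h0. The admissible box is: g ∈ [0, 50] nS,
E_Ca ∈ [20, 150] mV, E_K ∈ [-100, 0] mV, E_L ∈ [-80, 30] mV, every
V_half ∈ [-90, 0] mV, activation slopes in (0, 30] mV, inactivation and Kir
slopes in [-30, 0) mV, τ ∈ (0, 15] ds, x0 ∈ [0, 1], C ∈ (0, 10]. Open
interval ends are represented numerically with a 1e-3 margin so boundary
clipping can never produce a division-by-zero parameterisation.

## Steady-state current and bifurcation structure

With gates at equilibrium the total membrane current reduces to the scalar
curve I_inf(V) = Σ g · m_inf^a(V) h_inf^b(V) (V - E); its intersections with
the line I = const are exactly the equilibria of the full system, so the
curve's shape fixes the resting-state bifurcation diagram with the injected
current as parameter. A monotonically increasing I_inf gives one (globally
attracting) equilibrium for every I — near-linear graded responses. An
N-shaped curve gives a saddle-node fold pair: as I rises, a stable and an
unstable equilibrium coalesce and annihilate, producing bistable voltage
jumps.

Numerics:

* dI_inf/dV is computed analytically by chain rule
  (d(x^a)/dV = a x^a (1 - x)/k per gate), validated against central
  differences in the tests.
* Equilibrium finding partitions the search window at the local extrema of
  I_inf (refined sign changes of the analytic derivative on a dense grid,
  default 14401 points on [-120, 60] mV); the curve is monotone on each
  segment, so each segment holds at most one root, located by Brent's method
  to 1e-6 mV. This remains robust for near-tangent root pairs close to a
  fold, which a plain sign-change scan at the same grid resolution misses.
* Stability is classified from the eigenvalues of the full 3-state Jacobian
  (finite differences) at the equilibrium, with a 1e-8 tolerance on real
  parts; the scalar sign-of-slope criterion is exposed separately as a
  cross-check, and the two agree on all tested fixtures.
* Fold currents are I_inf evaluated at the refined extrema, sorted
  ascending; the equilibrium-search window is deliberately wider
  ([-120, 60] mV) than the shape-classification window so folds just outside
  the data range are still found.
* Shape classification follows a fixed recipe on [-100, 50] mV: the analytic
  derivative is evaluated at 1501 uniform points, signs within ±1e-9 are
  discarded, runs of equal sign are compressed, and the pattern (+) is
  `monotonic`, (+, -, +) is `n_shape`, anything else `other`.

## Cost functions

**Voltage (primary).** For each stimulus the model is simulated from
(V0, m0, h0) on the recording grid and scored by the per-trace RMSE divided
by that trace's noise level σ_I, averaged over stimuli. σ_I is the sample
standard deviation over a flat window at the end of the trace (default: the
final 10%, 1250 samples at the full 12500-sample protocol); σ values travel
with the dataset files so scores are reproducible without re-estimation. V0
is fixed from the data; m0 and h0 are free parameters of the fit, which
matters for bistable cells where the attained branch depends on the initial
state. A failed integration scores +inf, so optimisers discard the
candidate.

**Steady state (secondary).** The analytic I_inf is compared with the
cross-cell mean current at each holding voltage, each deviation normalised
by that point's standard deviation and averaged over the grid (per-point
normalised deviation). A single-RMSE-over-the-grid variant is available via
a switch; the per-point form is the default. f_inf depends only on θ_SS —
exactly invariant to τ, C and the initial gate states.

## Simulation back ends

* **Reference path** (`simulate_current_clamp`, `simulate_voltage_clamp`):
  scipy's LSODA with rtol 1e-8 / atol 1e-10, sampled on the protocol grid
  t_k = k·Δt, k = 0..N-1 (span 50 ds at Δt = 0.004 ds gives N = 12500).
  Deterministic for fixed inputs; validated against an independently written
  fixed-step RK4 oracle and against closed forms (RC relaxation, equilibrium
  flatness).
* **Population path** (`fastsim`): fitting evaluates thousands of candidate
  models per generation, so trials are integrated by an operator-splitting
  exponential-Euler scheme — gates relax exactly toward their frozen-voltage
  Boltzmann targets, then the voltage takes an exact step of
  dV/dt = -(g_tot/C)(V - V_target) with coefficients frozen over the step.
  The scheme is unconditionally stable on the whole admissible box:
  parameters that make the membrane or gates faster than the step snap to
  quasi-steady values instead of diverging. It is first-order accurate; at
  the default fitting step (0.04 ds) the error against LSODA is ~0.01-0.03 mV
  on smooth traces and largest (order 1 mV, transiently) around bistable
  jump onsets, well below the fitted noise scale. A numba-compiled kernel
  serves per-candidate evaluation; a pure-numpy vectorised implementation is
  the fallback and the two are cross-checked to 1e-13 in the tests.

## Evolutionary fitting

Single-objective DE (`de_single`) is classic generation-synchronous
DE/rand/1/bin with greedy one-to-one replacement (trial replaces target iff
not worse). Mutant components leaving the box are set to the closest bound.

The multi-objective engine (`demo_rand_best_biased`) is a DEMO variant with
two primary-objective biases: the initial population is seeded with the
optimum of a preliminary standalone single-objective run, and mutation
anchors to the current best primary-objective individual
(rand-to-best/1: v = x_r1 + F(x_best - x_r1) + F(x_r2 - x_r3); best/1 is
available behind a flag). Crossover is binomial with a guaranteed mutant
component. Selection per target: a dominating (or objective-identical) trial
replaces the target, a dominated trial is discarded, an incomparable one is
appended; the population is truncated back to NP at generation end by
non-dominated sorting and crowding distance, never discarding the
primary-objective best. Two selection schedules exist: *immediate* (default;
replacements and appends take effect within the generation, so improved
individuals immediately serve as parents) and *synchronous* (all NP trials
built from the generation-start snapshot and batch-evaluated). Immediate
converges markedly faster at small population sizes and is the
published-algorithm reading; synchronous is kept for vectorised batch
evaluation.

Control parameters: NP = 600, F = 1.5, CR = 0.3, 2000 generations and 10
independent runs by default — the values recommended for the full-size
study. Control parameters are meant to be re-tuned per setting; see the
scaled study below. Each run draws an independent RNG stream from the master
seed, runs may execute concurrently (joblib), and results are independent of
scheduling order; a fixed master seed reproduces the final Pareto set
bit-for-bit.

## Four-step selection

1. **Split.** Traces for -15..25 pA plus the steady-state table train the
   models; the 30 pA trace is the validation set; the 35 pA trace is the
   test set, scored for reporting only. The held-out traces are the highest
   stimuli because deterioration under the objective conflict concentrates
   beyond the trained range.
2. **Pool.** The final populations of the independent runs are pooled
   (NP × runs candidates; 6000 at full scale) and reduced to the
   non-dominated set S. The package's filter is an O(n log n) sort-and-sweep,
   tested against the O(n²) pairwise definition.
3. **Shape filter.** S is reduced to S1, the members whose steady-state
   curve has the class-appropriate shape (monotonic for RIM/AIY, N-shape for
   AFD) under the classification recipe above. An empty S1 raises an
   explicit "no admissible solution" error advising more runs.
4. **Validate.** Every member of S1 is scored on the validation trace alone
   (|I| = 1); the minimiser is selected, ties broken by lower f_inf, then
   lower index. The test trace never influences any selection step — the
   tests corrupt it and assert the selection is unchanged.

The preliminary bias stage is executed once per independent run (own RNG
stream) rather than once globally: each run is a complete execution of the
biased algorithm. This decorrelates the runs' search basins, which matters
for monotonic targets where a single shared bias individual can pull every
run into a spuriously N-shaped basin and empty S1. A shared-bias mode
remains available (`bias_per_run=False`).

## Synthetic data

Published voltage traces exist only as figures, so quantitative fitting
tests run on synthetic data; the packaged steady-state table (RIM 16 points
on -100..50 mV, AIY 18 on -120..50, AFD 17 on -110..50; cross-cell means of
n = 3/7/3 cells) is the only real-data fixture and is used for f_inf scoring
and shape demonstrations. Its per-point standard deviations were not
published; the fixture synthesises σ_VH = max(0.05·|I_mean|, 0.5 pA), stated
in its metadata.

Ground truths are drawn by rejection sampling from a physiological sub-box
(conductances of a few nS, reversals near ionic values, subthreshold gate
midpoints, τ of 0.2-5 ds, C of 0.5-3 pA·ds/mV — chosen so the protocol's
-15..35 pA steps produce deflections on the tens-of-mV scale of the
recordings) until the steady-state curve has the requested shape, the rest
state lies in a plausible range, and — for bistable truths — the
depolarising fold falls inside the stimulated current range (0, 30) pA so
jumps actually occur during the protocol. Initial gate states are pinned to
their equilibria at rest. Two frozen reference truths (one near-linear
RIM-class, one bistable AFD-class) are shipped as deterministic
seed-wrapped draws.

Synthetic recordings add iid Gaussian noise: per-sample voltage noise
(default sd 0.5 mV, the scale of patch-clamp noise relative to graded
signals) and per-cell current noise on clamp steady states (default sd 5 pA,
reflecting the sizable cell-to-cell variability of published I-V data),
averaged over n_cells pseudo-cells (default 3). The dataset σ_VH is the
across-cell sample sd floored at max(0.05·|I_mean|, 0.5 pA) — with 3 cells
the raw sample sd is itself very noisy, and the floor mirrors the packaged
table's convention. The noise model is stationary and white; real recordings
contain drift, correlated noise and series-resistance artefacts, so passing
recovery tests demonstrate identifiability under the stated noise model, not
under all experimental conditions. Steady-state points are measured as the
mean current over the last 0.5 ds (50 ms) of a clamp step long enough for
the slowest gate to equilibrate (16·τ_max + 1 ds).

## The reduced-size study

Desk-scale experiments (tests and the acceptance script) run the complete
pipeline at NP = 60, 300 DEMO generations, 3 independent runs, with a
300-generation rand-to-best/1 preliminary stage, on a shortened protocol
(span 10 ds, Δt = 0.04 ds, i.e. N = 250 samples per trace). At a population
a tenth of the recommended size the published scale factor over-explores, so
the scaled study re-tunes it to F = 0.7 (the canonical DE choice), keeping
CR = 0.3; `nonspike.pipeline.scaled_config` freezes this configuration.
Under it, the pipeline recovers the reference ground truths' shape class and
steady-state curve (mean noise-normalised deviation < 2) in ≈ 4-5 of 5
replicates per behaviour, at a few minutes per replicate on one CPU.

## Known limitations

* Single-compartment models only; no spatial structure.
* No spiking (fast sodium) channels; the channel library is exactly the four
  types above.
* The population integrator's first-order accuracy shifts bistable jump
  times by up to a few samples at the fitting step; final reported scores
  can be recomputed with the reference solver.
* The shape filter is a hard qualitative gate: shallow spurious N-shapes
  statistically consistent with noisy steady-state data are rejected rather
  than penalised, so monotonic targets occasionally yield an empty S1 at
  small run counts (the error message advises more runs).
* No continuation of limit cycles or Hopf bifurcations; the non-spiking
  models in scope have no oscillatory regime.
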