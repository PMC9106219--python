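"""Bound-constrained differential evolution, single- and multi-objective.

The single-objective engine is classic DE (default DE/rand/1/bin) with greedy
one-to-one replacement.  The multi-objective engine is a DEMO variant,
DEMO/rand/best/biased: dominance-based replacement (a trial that dominates
its target replaces it, a dominated trial is discarded, an incomparable one
is appended) followed by non-dominated-sorting + crowding-distance truncation
back to NP, with two tailorings that favour the primary objective —

* the initial population may be seeded (biased) with the optimum of a
  preliminary standalone single-objective run, and
* mutation greedily anchors trial vectors to the current best individual on
  the primary objective (rand-to-best/1 by default).

Mutant components that leave the feasible box are set to the closest
boundary value.  Both engines are generation-synchronous: all NP trials are
built from the generation-start population, batch-evaluated, then selection
is applied target by target — which lets the ODE-based objectives evaluate
the entire trial population in one vectorised pass.

Objectives are batch callables mapping a (B, D) genome array to a (B,) value
array (single-objective) or (B, 2) pair array (bi-objective, minimisation on
both); candidates whose evaluation fails score +inf and are dominated by any
finite pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PARAM_NAMES

__all__ = [
    "Bounds",
    "Individual",
    "ParetoSet",
    "DEConfig",
    "clip_to_bounds",
    "dominates",
    "mutate",
    "crossover_bin",
    "de_single",
    "demo_rand_best_biased",
    "nondominated_filter",
    "nondominated_mask",
    "fast_non_dominated_sort",
    "crowding_distance",
    "default_bounds",
]

#: Numerical margin for bounds that are open in the biological box
#: (k_m in (0,30], k_h/k_Kir in [-30,0), tau in (0,15], C in (0,10]).
OPEN_EPS = 1e-3


@dataclass(frozen=True)
class Bounds:
    """Componentwise (min, max) box matching the genome layout."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(self.lower >= self.upper):
            raise ValueError("each lower bound must be < its upper bound")

    @property
    def dimension(self) -> int:
        return self.lower.size

    def contains(self, genomes) -> np.ndarray:
        g = np.atleast_2d(np.asarray(genomes, dtype=float))
        return np.all((g >= self.lower) & (g <= self.upper), axis=1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dimension))


def default_bounds() -> Bounds:
    """The biologically relevant parameter box (per-role bounds).

    Conductances in [0, 50] nS; E_Ca in [20, 150], E_K in [-100, 0],
    E_L in [-80, 30] mV; every V_half in [-90, 0] mV; activation slopes in
    (0, 30], inactivation/Kir slopes in [-30, 0) mV; time constants in
    (0, 15] ds; initial gate states in [0, 1]; capacitance in (0, 10].
    """
    lo, hi = {}, {}
    for g in ("g_Ca", "g_Kir", "g_K", "g_L"):
        lo[g], hi[g] = 0.0, 50.0
    lo["E_Ca"], hi["E_Ca"] = 20.0, 150.0
    lo["E_K"], hi["E_K"] = -100.0, 0.0
    lo["E_L"], hi["E_L"] = -80.0, 30.0
    for v in ("V_half_p", "V_half_Kir", "V_half_m", "V_half_h"):
        lo[v], hi[v] = -90.0, 0.0
    for k in ("k_p", "k_m"):
        lo[k], hi[k] = OPEN_EPS, 30.0
    for k in ("k_Kir", "k_h"):
        lo[k], hi[k] = -30.0, -OPEN_EPS
    for t in ("tau_m", "tau_h"):
        lo[t], hi[t] = OPEN_EPS, 15.0
    lo["C"], hi["C"] = OPEN_EPS, 10.0
    for x in ("m0", "h0"):
        lo[x], hi[x] = 0.0, 1.0
    return Bounds(np.array([lo[n] for n in PARAM_NAMES]),
                  np.array([hi[n] for n in PARAM_NAMES]))


@dataclass
class Individual:
    genome: np.ndarray
    objectives: tuple[float, ...] | float | None = None


@dataclass
class ParetoSet:
    """Mutually non-dominated individuals, sorted by primary objective."""

    members: list[Individual] = field(default_factory=list)

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def genomes(self) -> np.ndarray:
        return np.array([ind.genome for ind in self.members])

    def objectives(self) -> np.ndarray:
        return np.array([ind.objectives for ind in self.members])


@dataclass
class DEConfig:
    """Control parameters; published defaults NP=600, F=1.5, CR=0.3,
    2000 iterations, 10 independent runs."""

    np_size: int = 600
    F: float = 1.5
    CR: float = 0.3
    iterations: int = 2000
    runs: int = 10
    seed: int = 0
    strategy: str = "rand-to-best/1"
    selection: str = "immediate"     # DEMO only: immediate | synchronous

    def validate(self) -> None:
        if self.selection not in ("immediate", "synchronous"):
            raise ValueError("selection must be 'immediate' or 'synchronous'")
        if self.np_size < 4:
            raise ValueError("population size NP must be >= 4")
        if not (0.0 <= self.CR <= 1.0):
            raise ValueError("crossover rate CR must lie in [0, 1]")
        if self.F <= 0:
            raise ValueError("scale factor F must be > 0")
        if self.iterations < 0 or self.runs < 1:
            raise ValueError("iterations must be >= 0 and runs >= 1")


def clip_to_bounds(genome, bounds: Bounds):
    """Replace each out-of-range component by its nearest bound."""
    return np.clip(np.asarray(genome, dtype=float), bounds.lower, bounds.upper)


def dominates(u, v) -> bool:
    """Pareto dominance under minimisation: u <= v componentwise, < somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return bool(np.all(u <= v) and np.any(u < v))


def mutate(population, target_index: int, strategy: str, F: float,
           bounds: Bounds, rng: np.random.Generator,
           best_index: int | None = None) -> np.ndarray:
    """Build a mutant genome; out-of-box components clip to the closest bound.

    Strategies: ``rand-to-best/1`` (default): x_r1 + F(x_best - x_r1)
    + F(x_r2 - x_r3); ``best/1``: x_best + F(x_r1 - x_r2); ``rand/1``:
    x_r1 + F(x_r2 - x_r3).  The random indices are distinct and differ from
    the target.
    """
    pop = np.asarray(population, dtype=float)
    NP = pop.shape[0]
    if NP < 4:
        raise ValueError("mutation requires a population of at least 4")
    candidates = np.delete(np.arange(NP), target_index)
    if strategy == "rand-to-best/1":
        if best_index is None:
            raise ValueError("rand-to-best/1 requires best_index")
        r1, r2, r3 = rng.choice(candidates, size=3, replace=False)
        v = pop[r1] + F * (pop[best_index] - pop[r1]) + F * (pop[r2] - pop[r3])
    elif strategy == "best/1":
        if best_index is None:
            raise ValueError("best/1 requires best_index")
        r1, r2 = rng.choice(candidates, size=2, replace=False)
        v = pop[best_index] + F * (pop[r1] - pop[r2])
    elif strategy == "rand/1":
        r1, r2, r3 = rng.choice(candidates, size=3, replace=False)
        v = pop[r1] + F * (pop[r2] - pop[r3])
    else:
        raise ValueError(f"unknown mutation strategy: {strategy!r}")
    return clip_to_bounds(v, bounds)


def crossover_bin(target, mutant, CR: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with one guaranteed mutant component (j_rand)."""
    if not (0.0 <= CR <= 1.0):
        raise ValueError("CR must lie in [0, 1]")
    target = np.asarray(target, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    mask = rng.random(target.size) < CR
    mask[rng.integers(target.size)] = True
    return np.where(mask, mutant, target)


# ---------------------------------------------------------------------------
# non-dominated sorting machinery


def nondominated_mask(objectives) -> np.ndarray:
    """Boolean mask of the non-dominated points of a bi-objective cloud.

    Sort-and-sweep: after ordering by (f1, f2), a point survives iff its f2 is
    the minimum of its f1-group and strictly below every f2 seen at smaller
    f1.  O(n log n); the O(n^2) pairwise definition serves as test oracle.
    """
    objs = np.asarray(objectives, dtype=float)
    n = objs.shape[0]
    f1, f2 = objs[:, 0], objs[:, 1]
    order = np.lexsort((f2, f1))
    keep = np.zeros(n, dtype=bool)
    running_min = np.inf
    first_group = True
    i = 0
    while i < n:
        j = i
        while j < n and f1[order[j]] == f1[order[i]]:
            j += 1
        group_min = f2[order[i]]          # group is sorted by f2
        group_survives = first_group or group_min < running_min
        if group_survives:
            for idx in order[i:j]:
                keep[idx] = f2[idx] == group_min
        running_min = min(running_min, group_min)
        first_group = False
        i = j
    return keep


def nondominated_filter(individuals) -> ParetoSet:
    """Remove every individual dominated by another; order by primary objective."""
    members = list(individuals)
    if not members:
        return ParetoSet([])
    objs = np.array([ind.objectives for ind in members], dtype=float)
    keep = nondominated_mask(objs)
    kept = [members[i] for i in np.nonzero(keep)[0]]
    kept.sort(key=lambda ind: (ind.objectives[0], ind.objectives[1]))
    return ParetoSet(kept)


def _domination_matrix(objs: np.ndarray) -> np.ndarray:
    f1, f2 = objs[:, 0], objs[:, 1]
    le = (f1[:, None] <= f1[None, :]) & (f2[:, None] <= f2[None, :])
    lt = (f1[:, None] < f1[None, :]) | (f2[:, None] < f2[None, :])
    return le & lt


def fast_non_dominated_sort(objectives) -> list[np.ndarray]:
    """NSGA-II style front peeling; returns index arrays, best front first."""
    objs = np.asarray(objectives, dtype=float)
    dom = _domination_matrix(objs)                 # dom[i, j]: i dominates j
    n_dominating = dom.sum(axis=0).astype(int)
    remaining = np.ones(objs.shape[0], dtype=bool)
    fronts = []
    while remaining.any():
        front = remaining & (n_dominating == 0)
        if not front.any():        # safeguard (cannot occur for finite inputs)
            front = remaining.copy()
        fronts.append(np.nonzero(front)[0])
        remaining &= ~front
        n_dominating -= dom[front].sum(axis=0)
    return fronts


def crowding_distance(objectives) -> np.ndarray:
    """Crowding distance within one front (boundary points get +inf)."""
    objs = np.asarray(objectives, dtype=float)
    n = objs.shape[0]
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(objs.shape[1]):
        vals = objs[:, j]
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        rng_j = vals[order[-1]] - vals[order[0]]
        if rng_j <= 0 or not np.isfinite(rng_j):
            continue
        dist[order[1:-1]] += (vals[order[2:]] - vals[order[:-2]]) / rng_j
    return dist


def _truncate(genomes, objs, NP: int):
    """Keep NP individuals by front rank then crowding; the primary-objective
    best is always retained."""
    fronts = fast_non_dominated_sort(objs)
    best = int(np.lexsort((objs[:, 1], objs[:, 0]))[0])
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= NP:
            chosen.extend(front.tolist())
        else:
            room = NP - len(chosen)
            cd = crowding_distance(objs[front])
            order = np.argsort(-cd, kind="stable")
            chosen.extend(front[order[:room]].tolist())
            break
    if best not in chosen:
        chosen[-1] = best
    chosen = sorted(chosen)
    return genomes[chosen], objs[chosen]


# ---------------------------------------------------------------------------
# engines


def _demo_generation_synchronous(objective, bounds, config, pop, objs, rng):
    """One DEMO generation: all trials built from the generation snapshot."""
    NP = config.np_size
    best_index = int(np.lexsort((objs[:, 1], objs[:, 0]))[0])
    trials = np.empty((NP, bounds.dimension))
    for i in range(NP):
        mutant = mutate(pop, i, config.strategy, config.F, bounds, rng,
                        best_index)
        trials[i] = crossover_bin(pop[i], mutant, config.CR, rng)
    trial_objs = np.asarray(objective(trials), dtype=float)
    extra_g, extra_o = [], []
    for i in range(NP):
        t, u = trial_objs[i], objs[i]
        if dominates(t, u) or np.array_equal(t, u):
            pop[i] = trials[i]
            objs[i] = t
        elif dominates(u, t):
            continue
        else:
            extra_g.append(trials[i])
            extra_o.append(t)
    if extra_g:
        pop = np.vstack([pop, np.array(extra_g)])
        objs = np.vstack([objs, np.array(extra_o)])
    return pop, objs


def _demo_generation_immediate(objective, bounds, config, pop, objs, rng):
    """One DEMO generation with immediate replacement/appending: each of the
    NP parents serves as target in turn against a freshly built and evaluated
    trial, and the growing population (including this generation's survivors)
    supplies the mutation parents and the primary-objective best."""
    NP = config.np_size
    pop = list(pop)
    objs = list(objs)
    for i in range(NP):
        arr = np.asarray(pop)
        oarr = np.asarray(objs)
        best_index = int(np.lexsort((oarr[:, 1], oarr[:, 0]))[0])
        mutant = mutate(arr, i, config.strategy, config.F, bounds, rng,
                        best_index)
        trial = crossover_bin(pop[i], mutant, config.CR, rng)
        t = np.asarray(objective(trial[None, :]), dtype=float)[0]
        u = objs[i]
        if dominates(t, u) or np.array_equal(t, u):
            pop[i] = trial
            objs[i] = t
        elif dominates(u, t):
            continue
        else:
            pop.append(trial)
            objs.append(t)
    return np.asarray(pop), np.asarray(objs)


def de_single(objective, bounds: Bounds, config: DEConfig,
              rng: np.random.Generator | None = None,
              init_population=None, return_population: bool = False):
    """Single-objective DE with greedy one-to-one replacement.

    ``objective`` maps a (B, D) genome array to (B,) values.  Every
    individual serves once as target per generation; a trial replaces its
    target iff its objective is <= the target's.  Returns the best Individual
    of the final population (optionally the final population too).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    NP = config.np_size
    strategy = config.strategy
    if init_population is None:
        pop = bounds.sample(rng, NP)
    else:
        pop = np.array(init_population, dtype=float)
    vals = np.asarray(objective(pop), dtype=float)
    for _ in range(config.iterations):
        best_index = int(np.argmin(vals))
        trials = np.empty_like(pop)
        for i in range(NP):
            mutant = mutate(pop, i, strategy, config.F, bounds, rng, best_index)
            trials[i] = crossover_bin(pop[i], mutant, config.CR, rng)
        trial_vals = np.asarray(objective(trials), dtype=float)
        improved = trial_vals <= vals
        pop[improved] = trials[improved]
        vals[improved] = trial_vals[improved]
    best = int(np.argmin(vals))
    best_ind = Individual(pop[best].copy(), float(vals[best]))
    if return_population:
        return best_ind, pop, vals
    return best_ind


def demo_rand_best_biased(objective, bounds: Bounds, config: DEConfig,
                          bias_individual=None,
                          rng: np.random.Generator | None = None,
                          return_population: bool = False):
    """DEMO/rand/best/biased: bi-objective DE returning a Pareto set.

    ``objective`` maps (B, D) genomes to (B, 2) objective pairs
    (primary f_V first, both minimised).  ``bias_individual`` (a genome), if
    given, is placed exactly once in the initial population.  Selection per
    target: a dominating (or objective-identical) trial replaces the target,
    a dominated trial is discarded, an incomparable trial is appended; the
    population is then truncated back to NP by non-dominated sorting and
    crowding distance, never discarding the primary-objective best.

    With ``config.selection == "immediate"`` (default) replacements and
    appends take effect within the generation, so improved individuals and
    the updated primary-objective best immediately serve as parents; with
    ``"synchronous"`` all NP trials are built from the generation-start
    population and batch-evaluated at once.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    NP = config.np_size
    pop = bounds.sample(rng, NP)
    if bias_individual is not None:
        bias = np.asarray(bias_individual, dtype=float)
        if not bounds.contains(bias)[0]:
            raise ValueError("bias individual lies outside the bounds")
        pop[0] = bias
    objs = np.asarray(objective(pop), dtype=float)
    for _ in range(config.iterations):
        if config.selection == "immediate":
            pop, objs = _demo_generation_immediate(objective, bounds, config,
                                                   pop, objs, rng)
        else:
            pop, objs = _demo_generation_synchronous(objective, bounds, config,
                                                     pop, objs, rng)
        if pop.shape[0] > NP:
            pop, objs = _truncate(pop, objs, NP)
    individuals = [Individual(pop[i].copy(), (float(objs[i, 0]), float(objs[i, 1])))
                   for i in range(pop.shape[0])]
    pareto = nondominated_filter(individuals)
    if return_population:
        return pareto, individuals
    return pareto
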