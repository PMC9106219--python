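"""Differential evolution machinery: operators, engines, Pareto handling."""

from __future__ import annotations

import numpy as np
import pytest

import nonspike as ns
from nonspike.optimize import (
    Bounds,
    DEConfig,
    Individual,
    _demo_generation_immediate,
    _demo_generation_synchronous,
    _truncate,
    crowding_distance,
    fast_non_dominated_sort,
    nondominated_mask,
)


def _box(D, lo=-5.0, hi=5.0):
    return Bounds(np.full(D, lo), np.full(D, hi), tuple(f"x{i}" for i in range(D)))


def _sphere(G):
    return np.sum(np.asarray(G) ** 2, axis=1)


def _biobj(G):
    G = np.asarray(G)
    return np.column_stack([np.sum(G ** 2, axis=1), np.sum((G - 1) ** 2, axis=1)])


def _brute_force_front(objs):
    objs = np.asarray(objs, dtype=float)
    keep = np.ones(len(objs), dtype=bool)
    for i in range(len(objs)):
        for j in range(len(objs)):
            if i != j and np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i]):
                keep[i] = False
                break
    return keep


# ---------------------------------------------------------------------------
# bounds & operators


def test_default_bounds_match_biological_box(bounds):
    get = lambda n: (bounds.lower[list(bounds.names).index(n)],
                     bounds.upper[list(bounds.names).index(n)])
    for g in ("g_Ca", "g_Kir", "g_K", "g_L"):
        assert get(g) == (0.0, 50.0)
    assert get("E_Ca") == (20.0, 150.0)
    assert get("E_K") == (-100.0, 0.0)
    assert get("E_L") == (-80.0, 30.0)
    for v in ("V_half_p", "V_half_Kir", "V_half_m", "V_half_h"):
        assert get(v) == (-90.0, 0.0)
    for k in ("k_p", "k_m"):
        assert get(k)[0] == pytest.approx(0.0, abs=1e-2) and get(k)[1] == 30.0
    for k in ("k_Kir", "k_h"):
        assert get(k)[0] == -30.0 and get(k)[1] == pytest.approx(0.0, abs=1e-2)
    for t in ("tau_m", "tau_h"):
        assert get(t)[0] == pytest.approx(0.0, abs=1e-2) and get(t)[1] == 15.0
    assert get("C")[1] == 10.0 and get("C")[0] == pytest.approx(0.0, abs=1e-2)
    assert get("m0") == (0.0, 1.0) and get("h0") == (0.0, 1.0)
    assert bounds.dimension == 20


def test_clip_to_bounds():
    b = _box(3, -1.0, 2.0)
    np.testing.assert_array_equal(ns.clip_to_bounds([-3.0, 0.5, 9.0], b),
                                  [-1.0, 0.5, 2.0])
    inside = np.array([0.1, -0.9, 1.9])
    np.testing.assert_array_equal(ns.clip_to_bounds(inside, b), inside)


@pytest.mark.parametrize("u, v, expected", [
    ((1, 1), (2, 2), True),
    ((1, 2), (2, 1), False),
    ((2, 1), (1, 2), False),
    ((1, 1), (1, 1), False),
    ((1, 2), (1, 3), True),
])
def test_dominates(u, v, expected):
    assert ns.dominates(u, v) is expected


def test_mutate_formula_reductions():
    b = _box(4)
    rng = np.random.default_rng(0)
    pop = rng.uniform(-2, 2, size=(6, 4))
    # F = 0 with rand-to-best/1 collapses to x_r1 (some population member)
    m = ns.mutate(pop, 0, "rand-to-best/1", 0.0, b, np.random.default_rng(1),
                  best_index=3)
    assert any(np.array_equal(m, pop[i]) for i in range(6) if i != 0)
    # identical population: mutant equals the best individual
    same = np.tile(pop[2], (6, 1))
    m2 = ns.mutate(same, 1, "rand-to-best/1", 1.5, b, np.random.default_rng(2),
                   best_index=0)
    np.testing.assert_allclose(m2, pop[2])
    # reproducibility under a fixed seed
    a = ns.mutate(pop, 2, "rand/1", 0.8, b, np.random.default_rng(7))
    c = ns.mutate(pop, 2, "rand/1", 0.8, b, np.random.default_rng(7))
    np.testing.assert_array_equal(a, c)
    with pytest.raises(ValueError):
        ns.mutate(pop[:3], 0, "rand/1", 0.5, b, rng)


def test_crossover_edges_and_rate():
    rng = np.random.default_rng(0)
    target = np.zeros(20)
    mutant = np.ones(20)
    assert np.array_equal(ns.crossover_bin(target, mutant, 1.0, rng), mutant)
    # CR = 0: exactly one component (j_rand) from the mutant
    trial = ns.crossover_bin(target, mutant, 0.0, rng)
    assert trial.sum() == 1.0
    # empirical mutant fraction at CR = 0.3, D = 20: 0.3 + 0.7/20
    total = 0
    n = 100_000
    rng = np.random.default_rng(42)
    for _ in range(n):
        total += ns.crossover_bin(target, mutant, 0.3, rng).sum()
    assert total / (n * 20) == pytest.approx(0.3 + 0.7 / 20, abs=0.01)


# ---------------------------------------------------------------------------
# non-dominated filtering


def test_nondominated_filter_examples():
    inds = [Individual(np.array([float(i)]), o)
            for i, o in enumerate([(1, 2), (2, 1), (2, 2)])]
    kept = ns.nondominated_filter(inds)
    assert sorted(ind.objectives for ind in kept) == [(1, 2), (2, 1)]
    same = [Individual(np.array([float(i)]), (3.0, 3.0)) for i in range(4)]
    assert len(ns.nondominated_filter(same)) == 4


def test_nondominated_filter_matches_brute_force():
    rng = np.random.default_rng(5)
    objs = rng.uniform(0, 1, size=(500, 2))
    objs[::50] = objs[::25][:10]          # inject duplicates
    mask = nondominated_mask(objs)
    np.testing.assert_array_equal(mask, _brute_force_front(objs))


def test_fast_non_dominated_sort_and_crowding():
    objs = np.array([[1, 4], [2, 3], [3, 2], [4, 1],       # front 0
                     [2, 5], [3, 4], [5, 2],                # front 1
                     [6, 6]])                               # front 2
    fronts = fast_non_dominated_sort(objs)
    assert [sorted(f.tolist()) for f in fronts] == [[0, 1, 2, 3], [4, 5, 6], [7]]
    cd = crowding_distance(objs[fronts[0]])
    assert np.isinf(cd[0]) and np.isinf(cd[-1])
    assert np.all(cd[1:-1] > 0) and np.all(np.isfinite(cd[1:-1]))


def test_truncate_retains_primary_best():
    rng = np.random.default_rng(0)
    genomes = rng.uniform(size=(30, 2))
    objs = rng.uniform(size=(30, 2))
    g, o = _truncate(genomes, objs, 10)
    assert len(g) == 10
    assert o[:, 0].min() == objs[:, 0].min()


# ---------------------------------------------------------------------------
# single-objective engine


def test_de_single_solves_sphere():
    """Standard DE benchmark: 10-D sphere, NP=50, 500 generations."""
    b = _box(10)
    wins = 0
    for seed in range(10):
        best = ns.de_single(_sphere, b, DEConfig(50, 0.7, 0.9, 500, 1, 0, "rand/1"),
                            rng=np.random.default_rng(seed))
        wins += best.objectives < 1e-6
    assert wins >= 9


def test_de_single_monotone_best_and_feasible():
    b = _box(5)
    cfg = DEConfig(20, 0.7, 0.9, 40, 1, 0, "rand/1")
    rng = np.random.default_rng(1)
    pop = b.sample(rng, 20)
    vals = _sphere(pop)
    history = [vals.min()]
    from nonspike.optimize import crossover_bin, mutate
    for _ in range(cfg.iterations):
        trials = np.array([crossover_bin(pop[i],
                                         mutate(pop, i, "rand/1", cfg.F, b, rng),
                                         cfg.CR, rng) for i in range(20)])
        tv = _sphere(trials)
        imp = tv <= vals
        pop[imp] = trials[imp]
        vals[imp] = tv[imp]
        assert np.all(b.contains(pop))
        history.append(vals.min())
    assert np.all(np.diff(history) <= 0)


def test_de_config_validation():
    with pytest.raises(ValueError):
        DEConfig(np_size=3).validate()
    with pytest.raises(ValueError):
        DEConfig(CR=1.5).validate()
    with pytest.raises(ValueError):
        DEConfig(F=0.0).validate()
    with pytest.raises(ValueError):
        DEConfig(selection="bogus").validate()


# ---------------------------------------------------------------------------
# DEMO engine


def test_demo_returns_mutually_nondominated_set():
    b = _box(5, -2.0, 3.0)
    ps = ns.demo_rand_best_biased(_biobj, b, DEConfig(40, 0.7, 0.3, 60, 1, 0),
                                  rng=np.random.default_rng(0))
    objs = ps.objectives()
    assert np.all(_brute_force_front(objs))
    assert np.all(b.contains(ps.genomes()))


def test_demo_bias_individual_in_initial_population():
    b = _box(5, -2.0, 3.0)
    bias = np.full(5, 0.5)
    count = {"n": 0, "first": None}

    def spy(G):
        if count["first"] is None:
            count["first"] = np.asarray(G).copy()
        return _biobj(G)

    ns.demo_rand_best_biased(spy, b, DEConfig(30, 0.7, 0.3, 1, 1, 0),
                             bias_individual=bias, rng=np.random.default_rng(3))
    matches = np.all(count["first"] == bias, axis=1).sum()
    assert matches == 1
    with pytest.raises(ValueError):
        ns.demo_rand_best_biased(_biobj, b, DEConfig(30, 0.7, 0.3, 1, 1, 0),
                                 bias_individual=np.full(5, 99.0),
                                 rng=np.random.default_rng(3))


@pytest.mark.parametrize("gen_step", [_demo_generation_immediate,
                                      _demo_generation_synchronous])
def test_demo_generation_invariants(gen_step):
    """Population size is NP after truncation, all genomes feasible, and the
    primary-objective minimum never increases."""
    b = _box(5, -2.0, 3.0)
    cfg = DEConfig(24, 0.7, 0.3, 1, 1, 0)
    rng = np.random.default_rng(9)
    pop = b.sample(rng, 24)
    objs = _biobj(pop)
    best = objs[:, 0].min()
    for _ in range(25):
        pop, objs = gen_step(_biobj, b, cfg, pop, objs, rng)
        if len(pop) > 24:
            pop, objs = _truncate(pop, objs, 24)
        assert len(pop) == 24
        assert np.all(b.contains(pop))
        assert objs[:, 0].min() <= best + 1e-12
        best = objs[:, 0].min()


def test_demo_seed_reproducibility():
    b = _box(5, -2.0, 3.0)
    cfg = DEConfig(20, 0.7, 0.3, 30, 1, 0)
    a = ns.demo_rand_best_biased(_biobj, b, cfg, rng=np.random.default_rng(11))
    c = ns.demo_rand_best_biased(_biobj, b, cfg, rng=np.random.default_rng(11))
    np.testing.assert_array_equal(a.genomes(), c.genomes())
    np.testing.assert_array_equal(a.objectives(), c.objectives())


def _hypervolume(objs, ref=(4.0, 4.0)):
    objs = objs[np.lexsort((objs[:, 1], objs[:, 0]))]
    h, prev = 0.0, ref[1]
    for f1, f2 in objs:
        if f1 >= ref[0] or f2 >= prev:
            continue
        h += (ref[0] - f1) * (prev - f2)
        prev = f2
    return h


def test_demo_beats_random_search_on_convex_front():
    """With an equal evaluation budget, DEMO's front hypervolume exceeds a
    random-search baseline on the convex toy bi-objective, every seed."""
    b = _box(5, -2.0, 3.0)
    wins = 0
    for s in range(10):
        ps = ns.demo_rand_best_biased(_biobj, b, DEConfig(60, 0.7, 0.3, 150, 1, 0),
                                      rng=np.random.default_rng(1000 + s))
        R = b.sample(np.random.default_rng(2000 + s), 60 * 151)
        ro = _biobj(R)
        rnd = ro[nondominated_mask(ro)]
        wins += _hypervolume(ps.objectives()) > _hypervolume(rnd)
    assert wins == 10
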