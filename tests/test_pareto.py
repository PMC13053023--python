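"""Dominance, frontier extraction, mutation, evolution, and optimality."""

import numpy as np
import pytest

from modals_effcomm import (
    EvolutionConfig,
    Language,
    MeasuredLanguage,
    TradeoffPoint,
    dominates,
    enumerate_meanings,
    evolve,
    four_corner_exploration,
    mutate,
    naturalness,
    optimality,
    pareto_front,
    sample_language,
    score_optimality,
)
from modals_effcomm.pareto_optimization import normalization_ranges

from conftest import language, meaning


def _ml(comp, cost, name="x"):
    L = language(name, meaning(("weak", "epistemic")))
    return MeasuredLanguage(L, comp, cost, 1.0)


def test_dominates_cases():
    assert dominates(TradeoffPoint(1, 0.5), TradeoffPoint(2, 0.6))
    assert not dominates(TradeoffPoint(1, 0.5), TradeoffPoint(1, 0.5))
    assert not dominates(TradeoffPoint(1, 0.6), TradeoffPoint(2, 0.5))
    # orientation flip: under maximization the relation reverses
    assert dominates(TradeoffPoint(2, 0.6), TradeoffPoint(1, 0.5), objectives=("max", "max"))


def test_pareto_front_small_example():
    pool = [_ml(1, 0.9), _ml(2, 0.5), _ml(3, 0.6)]
    front = pareto_front(pool)
    assert [(m.complexity, m.cost) for m in front] == [(1, 0.9), (2, 0.5)]
    single = [_ml(4, 0.2)]
    assert pareto_front(single) == single
    with pytest.raises(ValueError):
        pareto_front([])


def _brute_force_front(pool, objectives=("min", "min")):
    return [
        m
        for m in pool
        if not any(dominates(o.point, m.point, objectives) for o in pool)
    ]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pareto_front_matches_all_pairs_filter(seed):
    """Sweep-based frontier equals the quadratic dominance filter."""
    rng = np.random.default_rng(seed)
    pool = [
        _ml(float(c), float(k))
        for c, k in zip(rng.integers(1, 30, size=200), rng.random(200).round(2))
    ]
    for objectives in [("min", "min"), ("max", "min"), ("min", "max"), ("max", "max")]:
        front = pareto_front(pool, objectives)
        brute = _brute_force_front(pool, objectives)
        key = lambda m: (m.complexity, m.cost)
        assert sorted(map(key, front)) == sorted(map(key, brute))
        # every non-member is dominated by some frontier member
        fr = {id(m) for m in front}
        for m in pool:
            if id(m) not in fr:
                assert any(dominates(f.point, m.point, objectives) for f in front)


def test_mutation_preserves_invariants(space):
    rng = np.random.default_rng(0)
    L = sample_language(space, 1, 1, rng)
    for _ in range(300):
        L = mutate(L, space, rng)
        assert L.size >= 1
        assert all(len(m) >= 1 for m in L.meanings())
        assert all(p in set(space.points) for m in L.meanings() for p in m)


def _measurer(space, table, need):
    from modals_effcomm import communicative_cost, language_complexity

    def fn(L):
        return float(language_complexity(L, table)), communicative_cost(L, need)

    return fn


def test_evolve_single_generation_is_plain_frontier(space, table3, need):
    rng = np.random.default_rng(1)
    pool = [sample_language(space, int(rng.integers(1, 6)), 0, rng, name=f"L{i}") for i in range(40)]
    fn = _measurer(space, table3, need)
    cfg = EvolutionConfig(population=40, generations=1, seed=9)
    frontier, explored = evolve(pool, fn, space, cfg)
    measured = [MeasuredLanguage(L, *fn(L), naturalness(L)) for L in pool]
    expected = {(m.complexity, m.cost) for m in pareto_front(measured)}
    assert {(m.complexity, m.cost) for m in frontier} == expected
    assert len(explored) <= len(pool)


def test_evolve_is_deterministic_under_seed(space, table3, need_est):
    rng = np.random.default_rng(4)
    sizes = [int(s) for s in rng.integers(1, 8, size=30)]
    pool = [sample_language(space, s, int(rng.integers(0, s + 1)), rng, name=f"L{i}") for i, s in enumerate(sizes)]
    fn = _measurer(space, table3, need_est)
    cfg = EvolutionConfig(population=50, generations=10, seed=77)
    f1, e1 = evolve(pool, fn, space, cfg)
    f2, e2 = evolve(pool, fn, space, cfg)
    assert [(m.complexity, m.cost, m.language.canonical_key()) for m in f1] == [
        (m.complexity, m.cost, m.language.canonical_key()) for m in f2
    ]
    assert len(e1) == len(e2)


def test_evolved_frontier_is_mutually_nondominated(space, table3, need_est):
    rng = np.random.default_rng(2)
    pool = [sample_language(space, int(rng.integers(1, 8)), 0, rng, name=f"L{i}") for i in range(50)]
    fn = _measurer(space, table3, need_est)
    frontier, explored = evolve(pool, fn, space, EvolutionConfig(population=60, generations=15, seed=5))
    for a in frontier:
        assert not any(dominates(b.point, a.point) for b in frontier)
    # and the frontier dominates-or-ties everything explored
    for m in explored:
        if (m.complexity, m.cost) not in {(f.complexity, f.cost) for f in frontier}:
            assert any(dominates(f.point, m.point) for f in frontier)


def test_four_corner_exploration_spreads_complexity(space, table3, need_est):
    rng = np.random.default_rng(8)
    pool = [sample_language(space, int(rng.integers(1, 6)), 1, rng, name=f"L{i}") for i in range(30)]
    fn = _measurer(space, table3, need_est)
    cfg = EvolutionConfig(population=40, generations=8, seed=3)
    frontiers, union = four_corner_exploration(pool, fn, space, cfg)
    assert set(frontiers) == {("min", "min"), ("min", "max"), ("max", "min"), ("max", "max")}
    keys = [m.language.canonical_key() for m in union]
    assert len(keys) == len(set(keys))
    mean_max = np.mean([m.complexity for m in frontiers[("max", "max")]])
    mean_min = np.mean([m.complexity for m in frontiers[("min", "min")]])
    assert mean_max > mean_min


def test_optimality_scoring():
    frontier = [_ml(0.0, 0.0)]
    ranges = ((0.0, 1.0), (0.0, 1.0))
    on_front = optimality(TradeoffPoint(0.0, 0.0), frontier, ranges)
    assert on_front == pytest.approx(1.0)
    worst_e = optimality(TradeoffPoint(1.0, 1.0), frontier, ranges, metric="euclidean")
    worst_m = optimality(TradeoffPoint(1.0, 1.0), frontier, ranges, metric="manhattan")
    assert worst_e == pytest.approx(0.0)
    assert worst_m == pytest.approx(0.0)


def test_metric_normalization_orders_optimality():
    """Each metric's distance is divided by its unit-square maximum (2 for
    L1, sqrt(2) for L2); since d_L1 <= sqrt(2) d_L2, normalized Manhattan
    distance never exceeds normalized Euclidean, so Manhattan optimality is
    the more generous score."""
    rng = np.random.default_rng(0)
    frontier = [_ml(float(c), float(k)) for c, k in zip([1, 3, 6], [0.8, 0.4, 0.1])]
    ranges = normalization_ranges(frontier + [_ml(10.0, 1.0)])
    for _ in range(100):
        p = TradeoffPoint(float(rng.uniform(1, 10)), float(rng.random()))
        e = optimality(p, frontier, ranges, "euclidean")
        m = optimality(p, frontier, ranges, "manhattan")
        assert m >= e - 1e-12
        assert 0.0 <= m <= 1.0 and 0.0 <= e <= 1.0


def test_score_optimality_frontier_members_hit_one():
    pool = [_ml(1, 0.9), _ml(2, 0.5), _ml(3, 0.6), _ml(8, 0.95)]
    frontier = pareto_front(pool)
    scores = score_optimality(pool, frontier)
    for m in pool:
        if m in frontier:
            assert m.optimality == pytest.approx(1.0)
        else:
            assert m.optimality < 1.0
        assert 0.0 <= m.optimality <= 1.0
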