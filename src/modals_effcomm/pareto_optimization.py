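"""Pareto-frontier estimation for the complexity/cost trade-off.

Languages are points in a two-dimensional trade-off plane (complexity on
the x-axis, communicative cost on the y-axis, both to be minimized).  The
frontier is estimated with a mutation-only evolutionary algorithm with
dominance elitism: each generation keeps the non-dominated languages and
refills the population with offspring obtained by 1..max_mutations random
mutations (add/remove/interchange a modal; add/remove a single force-flavor
pair inside a modal).  Exploration of the whole plane additionally runs the
same algorithm toward each of the four min/max corners.

A language's *optimality* is one minus its minimum distance to a frontier
point, after min-max normalizing the complexity axis by the pooled sample's
observed range and dividing by the metric's maximal distance on the unit
square (sqrt(2) for Euclidean, 2 for Manhattan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .meaning_space import MeaningSpace, ModalMeaning, enumerate_meanings
from .typology_io import Language
from .universals import naturalness

__all__ = [
    "TradeoffPoint",
    "EvolutionConfig",
    "MeasuredLanguage",
    "dominates",
    "pareto_front",
    "mutate",
    "evolve",
    "four_corner_exploration",
    "normalization_ranges",
    "optimality",
    "score_optimality",
]

OBJECTIVES = ("min", "max")


@dataclass(frozen=True)
class TradeoffPoint:
    complexity: float
    cost: float


@dataclass(frozen=True)
class EvolutionConfig:
    population: int = 2000
    generations: int = 200
    max_mutations: int = 5
    seed: int = 0
    objectives: tuple[str, str] = ("min", "min")

    def __post_init__(self) -> None:
        if self.population < 1 or self.generations < 1:
            raise ValueError("population and generations must be >= 1")
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")
        if any(o not in OBJECTIVES for o in self.objectives):
            raise ValueError(f"objectives must be in {OBJECTIVES}")


@dataclass
class MeasuredLanguage:
    """A language with its trade-off coordinates and universal scores."""

    language: Language
    complexity: float
    cost: float
    naturalness: float
    optimality: float | None = None

    @property
    def point(self) -> TradeoffPoint:
        return TradeoffPoint(self.complexity, self.cost)


def _oriented(p: TradeoffPoint, objectives: tuple[str, str]) -> tuple[float, float]:
    cx = p.complexity if objectives[0] == "min" else -p.complexity
    cy = p.cost if objectives[1] == "min" else -p.cost
    return cx, cy


def dominates(a: TradeoffPoint, b: TradeoffPoint, objectives: tuple[str, str] = ("min", "min")) -> bool:
    """True iff ``a`` is at least as good as ``b`` on both axes and strictly
    better on at least one, under the given min/max orientation."""
    ax, ay = _oriented(a, objectives)
    bx, by = _oriented(b, objectives)
    return ax <= bx and ay <= by and (ax < bx or ay < by)


def pareto_front(
    measured: list[MeasuredLanguage], objectives: tuple[str, str] = ("min", "min")
) -> list[MeasuredLanguage]:
    """The non-dominated subset, ordered by (complexity, cost).

    Coincident points are mutually non-dominated and are all kept.
    """
    if not measured:
        raise ValueError("empty pool has no Pareto front")
    decorated = sorted(
        ((_oriented(m.point, objectives), i, m) for i, m in enumerate(measured)),
        key=lambda t: (t[0], t[1]),
    )
    front: list[MeasuredLanguage] = []
    best_y = math.inf
    last_kept: tuple[float, float] | None = None
    for coords, _, m in decorated:
        if coords == last_kept or coords[1] < best_y:
            front.append(m)
            best_y = min(best_y, coords[1])
            last_kept = coords
    front.sort(key=lambda m: (m.complexity, m.cost))
    return front


def _relabel(meanings: list[ModalMeaning], name: str) -> Language:
    modals = tuple((f"m{k + 1}", m) for k, m in enumerate(meanings))
    return Language(name, modals, provenance="evolved")


def mutate(L: Language, space: MeaningSpace, rng: np.random.Generator, max_tries: int = 50) -> Language:
    """Apply one random mutation; operators that would violate invariants
    (empty language, empty meaning, nothing to add) are re-sampled."""
    meanings = L.meanings()
    all_meanings = enumerate_meanings(space)
    full = frozenset(space.points)
    ops = ("add", "remove", "interchange", "add_point", "remove_point")
    for _ in range(max_tries):
        op = ops[int(rng.integers(len(ops)))]
        if op == "add":
            new = meanings + [all_meanings[int(rng.integers(len(all_meanings)))]]
        elif op == "remove":
            if len(meanings) <= 1:
                continue
            i = int(rng.integers(len(meanings)))
            new = meanings[:i] + meanings[i + 1:]
        elif op == "interchange":
            i = int(rng.integers(len(meanings)))
            new = list(meanings)
            new[i] = all_meanings[int(rng.integers(len(all_meanings)))]
        elif op == "add_point":
            i = int(rng.integers(len(meanings)))
            missing = sorted(full - meanings[i].points)
            if not missing:
                continue
            p = missing[int(rng.integers(len(missing)))]
            new = list(meanings)
            new[i] = ModalMeaning(meanings[i].points | {p})
        else:  # remove_point
            i = int(rng.integers(len(meanings)))
            pts = sorted(meanings[i].points)
            if len(pts) <= 1:
                continue
            p = pts[int(rng.integers(len(pts)))]
            new = list(meanings)
            new[i] = ModalMeaning(meanings[i].points - {p})
        return _relabel(new, L.name)
    return L  # pathological space; give up rather than loop forever


def evolve(
    initial_pool: list[Language],
    measure_fn,
    space: MeaningSpace,
    config: EvolutionConfig,
) -> tuple[list[MeasuredLanguage], list[MeasuredLanguage]]:
    """Run the evolutionary frontier search.

    ``measure_fn(language) -> (complexity, cost)`` supplies the objective
    coordinates.  Returns ``(frontier, explored)`` where ``explored`` holds
    every distinct language evaluated during the run (including the seed
    pool).  Fully reproducible under ``config.seed``.
    """
    if not initial_pool:
        raise ValueError("evolve needs a non-empty seed pool")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    explored: dict[tuple, MeasuredLanguage] = {}

    def measure(L: Language) -> MeasuredLanguage:
        key = L.canonical_key()
        hit = explored.get(key)
        if hit is None:
            comp, cost = measure_fn(L)
            hit = MeasuredLanguage(L, comp, cost, naturalness(L))
            explored[key] = hit
        return hit

    population = [measure(L) for L in initial_pool]
    for generation in range(config.generations):
        dominant = pareto_front(population, config.objectives)
        if generation == config.generations - 1:
            break
        n_offspring = max(config.population - len(dominant), 0)
        offspring: list[MeasuredLanguage] = []
        for j in range(n_offspring):
            parent = dominant[j % len(dominant)].language
            child = parent
            for _ in range(int(rng.integers(1, config.max_mutations + 1))):
                child = mutate(child, space, rng)
            offspring.append(measure(child))
        population = dominant + offspring
    return dominant, list(explored.values())


def four_corner_exploration(
    initial_pool: list[Language],
    measure_fn,
    space: MeaningSpace,
    config: EvolutionConfig,
) -> tuple[dict[tuple[str, str], list[MeasuredLanguage]], list[MeasuredLanguage]]:
    """Run the search toward all four min/max corners of the plane.

    Returns the per-corner frontiers and the deduplicated union of all
    languages explored across the four runs.
    """
    corners = [("min", "min"), ("min", "max"), ("max", "min"), ("max", "max")]
    seeds = np.random.SeedSequence(config.seed).spawn(len(corners))
    frontiers: dict[tuple[str, str], list[MeasuredLanguage]] = {}
    union: dict[tuple, MeasuredLanguage] = {}
    for corner, seed in zip(corners, seeds):
        run_cfg = replace(config, objectives=corner, seed=int(seed.generate_state(1)[0] % (2**31)))
        frontier, explored = evolve(initial_pool, measure_fn, space, run_cfg)
        frontiers[corner] = frontier
        for m in explored:
            union.setdefault(m.language.canonical_key(), m)
    return frontiers, list(union.values())


def normalization_ranges(
    measured: list[MeasuredLanguage], normalize_cost: bool = False
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Axis ranges used to place languages on the unit square.

    Complexity is min-max normalized by the pooled observed range; cost is
    taken as already lying in [0, 1] unless ``normalize_cost`` (used for
    measures in bits, e.g. IB cost).
    """
    comps = [m.complexity for m in measured]
    crange = (min(comps), max(comps))
    if normalize_cost:
        costs = [m.cost for m in measured]
        return crange, (min(costs), max(costs))
    return crange, (0.0, 1.0)


def _normalize(value: float, lo: float, hi: float) -> float:
    return (value - lo) / (hi - lo) if hi > lo else 0.0


def optimality(
    x: MeasuredLanguage | TradeoffPoint,
    frontier: list[MeasuredLanguage],
    ranges: tuple[tuple[float, float], tuple[float, float]],
    metric: str = "euclidean",
) -> float:
    """1 minus the normalized minimum distance to a frontier point, in [0, 1]."""
    if not frontier:
        raise ValueError("empty frontier")
    if metric not in ("euclidean", "manhattan"):
        raise ValueError(f"unknown metric {metric!r}")
    (clo, chi), (klo, khi) = ranges
    p = x.point if isinstance(x, MeasuredLanguage) else x
    px = _normalize(p.complexity, clo, chi)
    py = _normalize(p.cost, klo, khi)
    best = math.inf
    for f in frontier:
        fx = _normalize(f.complexity, clo, chi)
        fy = _normalize(f.cost, klo, khi)
        if metric == "euclidean":
            d = math.hypot(px - fx, py - fy)
        else:
            d = abs(px - fx) + abs(py - fy)
        best = min(best, d)
    max_d = math.sqrt(2.0) if metric == "euclidean" else 2.0
    return 1.0 - best / max_d


def score_optimality(
    pool: list[MeasuredLanguage],
    frontier: list[MeasuredLanguage],
    metric: str = "euclidean",
    normalize_cost: bool = False,
) -> list[float]:
    """Assign and return optimality for every language in ``pool``.

    Normalization ranges come from the pooled set together with the
    frontier, so frontier members score exactly 1.
    """
    ranges = normalization_ranges(pool + frontier, normalize_cost)
    scores = []
    for m in pool:
        m.optimality = optimality(m, frontier, ranges, metric)
        scores.append(m.optimality)
    return scores
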