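"""Shared fixtures and the independent shortest-formula oracle."""

from __future__ import annotations

import itertools
import math

import pytest

from modals_effcomm import (
    Language,
    MeaningPoint,
    ModalMeaning,
    build_space,
    complexity_table,
    estimated_need,
    uniform_need,
)


@pytest.fixture(scope="session")
def space():
    """The 2-force x 3-flavor space of the main analysis."""
    return build_space(["weak", "strong"], ["epistemic", "deontic", "circumstantial"])


@pytest.fixture(scope="session")
def space4():
    """The 2-force x 4-flavor space of the complexity worked examples."""
    return build_space(
        ["weak", "strong"], ["epistemic", "deontic", "circumstantial", "teleological"]
    )


@pytest.fixture(scope="session")
def need(space):
    return uniform_need(space)


@pytest.fixture(scope="session")
def need_est(space):
    return estimated_need(space)


@pytest.fixture(scope="session")
def table3(space):
    return complexity_table(space)


def meaning(*pairs) -> ModalMeaning:
    return ModalMeaning(MeaningPoint(fo, fl) for fo, fl in pairs)


def language(name, *meanings, provenance="synthetic") -> Language:
    return Language(name, tuple((f"m{i+1}", m) for i, m in enumerate(meanings)), provenance)


@pytest.fixture(scope="session")
def table2_meanings(space4):
    """The three worked-example modals over the 2x4 grid."""
    weak, strong = "weak", "strong"
    e, d, t = "epistemic", "deontic", "teleological"
    return {
        "may": meaning((weak, e), (weak, d)),
        "mought": meaning((weak, e), (strong, d)),
        "notcirc": meaning(*[(fo, fl) for fo in (weak, strong) for fl in (e, d, t)]),
    }


# --- independent shortest-formula oracle: two-level (DNF/CNF) set cover ---


def _products(space):
    """Minimal literal cost per denotation achievable by a single conjunction
    of (possibly negated) force/flavor atoms."""
    n = space.size
    full = (1 << n) - 1
    atom_masks = []
    nfl = len(space.flavors)
    for fi in range(len(space.forces)):
        atom_masks.append(sum(1 << (fi * nfl + j) for j in range(nfl)))
    for fj in range(nfl):
        atom_masks.append(sum(1 << (fi * nfl + fj) for fi in range(len(space.forces))))
    literals = [m for m in atom_masks] + [full & ~m for m in atom_masks]
    best: dict[int, int] = {}
    k = len(literals)
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            mask = full
            for i in combo:
                mask &= literals[i]
            if mask and (mask not in best or r < best[mask]):
                best.setdefault(mask, r)
    return best


def _min_cover(target: int, products: dict[int, int]) -> float:
    """Cheapest union of products equal to ``target`` (brute-force DP)."""
    useful = {m: c for m, c in products.items() if m & target == m}
    INF = math.inf
    # Dijkstra-flavored relaxation over covered subsets of the target
    import heapq

    heap = [(0.0, 0)]
    seen: dict[int, float] = {0: 0.0}
    while heap:
        c, covered = heapq.heappop(heap)
        if c > seen.get(covered, INF):
            continue
        if covered == target:
            return c
        for pm, pc in useful.items():
            nxt = covered | pm
            if c + pc < seen.get(nxt, INF):
                seen[nxt] = c + pc
                heapq.heappush(heap, (c + pc, nxt))
    return INF


def oracle_min_length(m: ModalMeaning, space) -> int:
    """Minimum LoT length by exhaustive two-level search.

    Takes the cheaper of the best disjunction-of-conjunctions (DNF) and,
    dually, the best conjunction-of-disjunctions (CNF, via covers of the
    complement with complemented clauses); single literals arise as
    one-product covers.  Implemented independently of the package's
    level-wise denotation search.
    """
    full = (1 << space.size) - 1
    target = space.mask(m.points)
    products = _products(space)
    dnf = _min_cover(target, products)
    # clause complements are products; the full meaning has no CNF with >= 1
    # clause short of a tautology, which the grammar cannot express atom-free
    cnf = _min_cover(full & ~target, products) if target != full else math.inf
    return int(min(dnf, cnf))
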