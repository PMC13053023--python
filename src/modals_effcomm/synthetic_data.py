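"""Generators for hypothetical and naturalistic modal inventories.

Two generators are provided.  The *stratified sampler* draws languages with
an exact (size, IFF-count) composition, uniformly within the IFF and
non-IFF meaning subsets, with replacement (so synonymy can arise); the pool
generator runs it over the full grid of sizes 1..10 crossed with IFF counts
0..size and deduplicates the result as multisets of meanings.  The
*naturalistic generator* emulates attested inventories: mostly-IFF meanings
biased toward low-complexity rectangles, with occasional synonym pairs, as
real modal systems show.

Exhaustive enumeration of languages is infeasible (there are more than
5 x 10^11 ten-modal multisets over the 63 meanings of the 2x3 space), hence
sampling throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meaning_space import MeaningPoint, MeaningSpace, ModalMeaning, enumerate_meanings
from .typology_io import Language
from .universals import iff_satisfied

__all__ = [
    "SamplerConfig",
    "iff_split",
    "sample_language",
    "generate_pool",
    "generate_naturalistic_inventories",
    "count_possible_languages",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Stratified-sampling grid: sizes 1..max_size x IFF counts 0..size."""

    max_size: int = 10
    n_per_cell: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_size <= 10:
            raise ValueError("max_size must be between 1 and 10")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


def count_possible_languages(n_meanings: int, size: int) -> int:
    """Number of size-``size`` multisets over ``n_meanings`` meanings."""
    return math.comb(n_meanings + size - 1, size)


def iff_split(space: MeaningSpace) -> tuple[list[ModalMeaning], list[ModalMeaning]]:
    """All meanings of the space split into (IFF, non-IFF), enumeration order."""
    iff, non = [], []
    for m in enumerate_meanings(space):
        (iff if iff_satisfied(m) else non).append(m)
    return iff, non


def sample_language(
    space: MeaningSpace,
    size: int,
    iff_count: int,
    rng: np.random.Generator,
    name: str = "sampled",
    provenance: str = "sampled",
) -> Language:
    """Draw a language with exactly ``iff_count`` IFF modals out of ``size``.

    Draws are uniform with replacement within each subset, so duplicate
    meanings (synonyms) can occur.
    """
    if not 0 <= iff_count <= size:
        raise ValueError(f"iff_count {iff_count} outside [0, {size}]")
    iff, non = iff_split(space)
    if iff_count > 0 and not iff:
        raise ValueError("space has no IFF meaning")
    if iff_count < size and not non:
        raise ValueError("space has no non-IFF meaning to draw from")
    chosen = [iff[i] for i in rng.integers(len(iff), size=iff_count)]
    chosen += [non[i] for i in rng.integers(len(non), size=size - iff_count)]
    modals = tuple((f"m{k + 1}", m) for k, m in enumerate(chosen))
    return Language(name, modals, provenance)


def generate_pool(space: MeaningSpace, config: SamplerConfig = SamplerConfig()) -> list[Language]:
    """Stratified sample over the (size, iff_count) grid, deduplicated.

    A root seed fans out to one child seed per grid cell, so the pool is
    reproducible regardless of cell order.  Languages identical as multisets
    of meanings are kept once (expression labels are generated and carry no
    content).
    """
    root = np.random.SeedSequence(config.seed)
    cells = [
        (size, iff_count)
        for size in range(1, config.max_size + 1)
        for iff_count in range(0, size + 1)
    ]
    children = root.spawn(len(cells))
    pool: dict[tuple, Language] = {}
    for (size, iff_count), child in zip(cells, children):
        rng = np.random.default_rng(child)
        for j in range(config.n_per_cell):
            L = sample_language(
                space, size, iff_count, rng, name=f"sampled-s{size}-i{iff_count}-{j}"
            )
            pool.setdefault(L.canonical_key(), L)
    return list(pool.values())


def _rectangle(space: MeaningSpace, rng: np.random.Generator) -> ModalMeaning:
    """A low-complexity IFF meaning: F x G with small axis subsets favored."""

    def axis_subset(labels: tuple[str, ...]) -> list[str]:
        sizes = np.arange(1, len(labels) + 1)
        w = 2.0 ** -sizes
        k = int(rng.choice(sizes, p=w / w.sum()))
        idx = rng.choice(len(labels), size=k, replace=False)
        return [labels[i] for i in sorted(idx)]

    F = axis_subset(space.forces)
    G = axis_subset(space.flavors)
    return ModalMeaning(MeaningPoint(fo, fl) for fo in F for fl in G)


def generate_naturalistic_inventories(
    space: MeaningSpace,
    n: int,
    rng: np.random.Generator,
    synonymy_rate: float = 0.15,
    iff_bias: float = 0.95,
    min_size: int = 2,
    max_size: int = 10,
) -> list[Language]:
    """Languages that emulate attested inventories.

    Each language has a size drawn uniformly from ``min_size..max_size``;
    its distinct meanings are IFF rectangles with probability ``iff_bias``
    (biased toward small, cheap rectangles) and arbitrary meanings
    otherwise.  Synonyms are then injected by replacing a Binomial(size-1,
    synonymy_rate) number of slots with duplicates of earlier meanings.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _, non = iff_split(space)
    all_meanings = enumerate_meanings(space)
    out = []
    for i in range(n):
        size = int(rng.integers(min_size, max_size + 1))
        n_dup = int(rng.binomial(size - 1, synonymy_rate)) if size > 1 else 0
        n_distinct = min(size - n_dup, len(all_meanings))
        distinct: list[ModalMeaning] = []
        seen = set()
        while len(distinct) < n_distinct:
            for _ in range(200):
                if non and rng.random() > iff_bias:
                    m = non[int(rng.integers(len(non)))]
                else:
                    m = _rectangle(space, rng)
                if m.points not in seen:
                    break
            else:  # tiny spaces can exhaust the biased support
                remaining = [m for m in all_meanings if m.points not in seen]
                m = remaining[int(rng.integers(len(remaining)))]
            seen.add(m.points)
            distinct.append(m)
        meanings = list(distinct)
        for _ in range(size - n_distinct):
            meanings.append(distinct[int(rng.integers(n_distinct))])
        modals = tuple((f"m{k + 1}", m) for k, m in enumerate(meanings))
        out.append(Language(f"synthetic-{i}", modals, provenance="synthetic"))
    return out
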