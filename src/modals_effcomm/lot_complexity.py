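"""Minimum-description-length complexity of modal meanings in a Boolean LoT.

The representation language has one propositional atom per force and per
flavor; the connectives are conjunction, disjunction, and negation applied
to atoms.  An atom denotes the set of grid points carrying its label (a row
for a force, a column for a flavor); connectives act as set intersection,
union, and complement.  The complexity of a meaning is the number of atom
occurrences (literals) in its shortest denoting formula, following the
Boolean-complexity tradition in concept learning; connectives are free and a
negated atom costs one.

The search enumerates denotations by increasing atom count: level 1 holds
all literals, and level c is built by conjoining/disjoining pairs of
already-minimal denotations whose costs sum to c.  Because any formula
splits into two subformulas whose denotations have at most their own cost,
the first level at which a denotation appears is its true minimum.  Within a
level the canonical enumeration order (positive atoms before negated ones,
forces before flavors, lower levels first) makes the returned formula a
deterministic tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from .meaning_space import MeaningSpace, ModalMeaning, NeedDistribution

__all__ = [
    "Formula",
    "ComplexityResult",
    "denotation",
    "minimal_formula",
    "complexity_table",
    "language_complexity",
    "vocabulary_size",
    "vocabulary_entropy",
]

DEFAULT_MAX_ATOMS = 8
_HARD_CAP = 16


@dataclass(frozen=True)
class Formula:
    """A Boolean LoT formula: an (optionally negated) atom, or an n-ary ∧/∨."""

    op: str  # "atom" | "and" | "or"
    label: str | None = None
    negated: bool = False
    args: tuple["Formula", ...] = ()

    @staticmethod
    def atom(label: str, negated: bool = False) -> "Formula":
        return Formula("atom", label=label, negated=negated)

    @staticmethod
    def combine(op: str, left: "Formula", right: "Formula") -> "Formula":
        """Connect two formulas, flattening nested same-op arguments."""
        if op not in ("and", "or"):
            raise ValueError(f"unknown connective {op!r}")
        args = (left.args if left.op == op else (left,)) + (
            right.args if right.op == op else (right,)
        )
        return Formula(op, args=args)

    @property
    def atom_count(self) -> int:
        if self.op == "atom":
            return 1
        return sum(a.atom_count for a in self.args)

    def to_string(self, ascii_ops: bool = False, abbrev: Mapping[str, str] | None = None) -> str:
        NOT, AND, OR = ("not ", " and ", " or ") if ascii_ops else ("¬", " ∧ ", " ∨ ")
        if self.op == "atom":
            name = abbrev.get(self.label, self.label) if abbrev else self.label
            return f"{NOT}{name}" if self.negated else name
        sep = AND if self.op == "and" else OR
        parts = [
            f"({a.to_string(ascii_ops, abbrev)})" if a.op in ("and", "or") else a.to_string(ascii_ops, abbrev)
            for a in self.args
        ]
        return sep.join(parts)

    def __str__(self) -> str:
        return self.to_string()


def _axis_masks(space: MeaningSpace) -> dict[str, int]:
    """Bitmask denotation of each (positive) force/flavor atom."""
    nfl = len(space.flavors)
    masks: dict[str, int] = {}
    for fi, fo in enumerate(space.forces):
        m = 0
        for fj in range(nfl):
            m |= 1 << (fi * nfl + fj)
        masks[fo] = m
    for fj, fl in enumerate(space.flavors):
        m = 0
        for fi in range(len(space.forces)):
            m |= 1 << (fi * nfl + fj)
        masks[fl] = m
    return masks


def _denotation_mask(f: Formula, space: MeaningSpace) -> int:
    axis = _axis_masks(space)
    # atoms may be written with the space's short names as well
    for full, short in space.atom_names().items():
        axis.setdefault(short, axis[full])
    full_mask = (1 << space.size) - 1

    def rec(g: Formula) -> int:
        if g.op == "atom":
            try:
                m = axis[g.label]
            except KeyError:
                raise ValueError(f"unknown atom label {g.label!r} for this space") from None
            return (full_mask & ~m) if g.negated else m
        acc = rec(g.args[0])
        for a in g.args[1:]:
            acc = acc & rec(a) if g.op == "and" else acc | rec(a)
        return acc

    return rec(f)


def denotation(f: Formula, space: MeaningSpace) -> ModalMeaning | None:
    """The set of points satisfying ``f``; ``None`` for an empty denotation."""
    mask = _denotation_mask(f, space)
    return space.meaning_from_mask(mask) if mask else None


@lru_cache(maxsize=None)
def _minimal_mask_table(space: MeaningSpace, max_atoms: int) -> dict[int, tuple[int, Formula]]:
    """mask -> (minimal atom count, witness formula), for all masks reachable
    within ``max_atoms`` atoms."""
    full = (1 << space.size) - 1
    axis = _axis_masks(space)
    literals: list[tuple[str, bool, int]] = []
    for label in space.forces + space.flavors:
        literals.append((label, False, axis[label]))
    for label in space.forces + space.flavors:
        literals.append((label, True, full & ~axis[label]))

    best: dict[int, tuple[int, Formula]] = {}
    levels: dict[int, list[int]] = {}
    first = []
    for label, neg, mask in literals:
        if mask and mask not in best:
            best[mask] = (1, Formula.atom(label, neg))
            first.append(mask)
    levels[1] = first

    target_count = (1 << space.size) - 1
    for cost in range(2, max_atoms + 1):
        fresh: list[int] = []
        for c1 in range(1, cost // 2 + 1):
            c2 = cost - c1
            for m1 in levels.get(c1, ()):
                for m2 in levels.get(c2, ()):
                    for op, mm in (("and", m1 & m2), ("or", m1 | m2)):
                        if mm and mm not in best:
                            best[mm] = (cost, Formula.combine(op, best[m1][1], best[m2][1]))
                            fresh.append(mm)
        levels[cost] = fresh
        if len(best) == target_count:
            break
    return best


@dataclass(frozen=True)
class ComplexityResult:
    """A meaning together with its shortest formula and its atom count."""

    meaning: ModalMeaning
    formula: Formula
    complexity: int


def minimal_formula(
    m: ModalMeaning, space: MeaningSpace, max_atoms: int = DEFAULT_MAX_ATOMS
) -> ComplexityResult:
    """Shortest LoT formula denoting exactly ``m``.

    Raises ``ValueError`` if no formula of at most ``max_atoms`` atoms
    denotes the meaning (the cap is too low for the space).
    """
    mask = space.mask(m.points)
    table = _minimal_mask_table(space, max_atoms)
    if mask not in table:
        raise ValueError(
            f"no formula with <= {max_atoms} atoms denotes {m!r}; raise max_atoms"
        )
    cost, formula = table[mask]
    return ComplexityResult(m, formula, cost)


def complexity_table(
    space: MeaningSpace, max_atoms: int | None = None
) -> dict[ModalMeaning, ComplexityResult]:
    """Minimal formulas for every one of the 2^n - 1 meanings of the space.

    With ``max_atoms=None`` the cap starts at 8 and doubles (up to 16) until
    every meaning is covered, so the returned table is always complete.
    """
    caps = [max_atoms] if max_atoms is not None else [DEFAULT_MAX_ATOMS, 12, _HARD_CAP]
    last_err: Exception | None = None
    for cap in caps:
        table = _minimal_mask_table(space, cap)
        if len(table) == (1 << space.size) - 1:
            return {
                space.meaning_from_mask(mask): ComplexityResult(
                    space.meaning_from_mask(mask), f, c
                )
                for mask, (c, f) in table.items()
            }
        last_err = ValueError(
            f"cap {cap} covers only {len(table)} of {(1 << space.size) - 1} meanings"
        )
    raise last_err


def language_complexity(L, table: Mapping[ModalMeaning, ComplexityResult]) -> int:
    """Language complexity: the sum of per-modal minimal formula lengths.

    Synonyms each count (the language is a multiset of modals).
    """
    total = 0
    for meaning in L.meanings():
        try:
            total += table[meaning].complexity
        except KeyError:
            raise KeyError(f"meaning {meaning!r} missing from complexity table") from None
    return total


def vocabulary_size(L) -> int:
    """Number of forms in the language, synonyms included."""
    return len(L.meanings())


def vocabulary_entropy(L, need: NeedDistribution) -> float:
    """Entropy H(M) in bits of modal use under the literal speaker.

    P(m) = sum_p P(p) P(m|p) with the speaker uniform over the modal tokens
    that can express p.  Points no modal covers contribute no mass (the
    result is the entropy of the resulting subdistribution, 0·log0 = 0).
    """
    meanings = L.meanings()
    use = [0.0] * len(meanings)
    for p, prob in need.prob.items():
        expressors = [i for i, mg in enumerate(meanings) if p in mg]
        if not expressors:
            continue
        share = prob / len(expressors)
        for i in expressors:
            use[i] += share
    return -sum(q * math.log2(q) for q in use if q > 0)
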