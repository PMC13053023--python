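"""Semantic universals for modals: IFF and SAV, and language naturalness.

A modal satisfies the Independence of Force and Flavor (IFF) when its
meaning is exactly the Cartesian product of the forces and flavors it can
express — force and flavor vary independently.  The older Single Axis of
Variability (SAV) universal requires variation on at most one axis.  A
language's *naturalness* is the fraction of its modal tokens satisfying IFF
(multiset-counted, so synonyms each count).
"""

from __future__ import annotations

from dataclasses import dataclass

from .meaning_space import MeaningPoint, ModalMeaning
from .typology_io import Language

__all__ = ["UniversalVerdict", "iff_satisfied", "sav_satisfied", "naturalness", "verdict"]


@dataclass(frozen=True)
class UniversalVerdict:
    meaning: ModalMeaning
    iff: bool
    sav: bool


def iff_satisfied(m: ModalMeaning) -> bool:
    """True iff the meaning equals fo(m) x fl(m)."""
    product = {MeaningPoint(fo, fl) for fo in m.forces() for fl in m.flavors()}
    return m.points == product


def sav_satisfied(m: ModalMeaning) -> bool:
    """True iff the modal varies on at most one axis (|fo|=1 or |fl|=1)."""
    return len(m.forces()) == 1 or len(m.flavors()) == 1


def verdict(m: ModalMeaning) -> UniversalVerdict:
    return UniversalVerdict(m, iff_satisfied(m), sav_satisfied(m))


def naturalness(L: Language) -> float:
    """Fraction of the language's modal tokens satisfying IFF."""
    meanings = L.meanings()
    return sum(iff_satisfied(m) for m in meanings) / len(meanings)
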