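"""Force-flavor meaning spaces, modal meanings, and communicative need.

The semantic space for modality is a grid of *force* (quantificational
strength: weak possibility vs. strong necessity) by *flavor* (the kind of
modality: epistemic, deontic, circumstantial, ...).  A single force-flavor
pair is the atomic unit a speaker may want to convey; a modal's meaning is a
non-empty set of such pairs.  A communicative need distribution assigns each
pair the probability that speakers need to express it.

The default space has forces {weak, strong} and flavors {epistemic, deontic,
circumstantial}, i.e. six meaning points, but spaces are fully configurable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MeaningPoint",
    "MeaningSpace",
    "ModalMeaning",
    "NeedDistribution",
    "build_space",
    "default_space",
    "enumerate_meanings",
    "force_projection",
    "flavor_projection",
    "uniform_need",
    "load_need",
    "estimated_need",
]

DEFAULT_FORCES = ("weak", "strong")
DEFAULT_FLAVORS = ("epistemic", "deontic", "circumstantial")


@dataclass(frozen=True, order=True)
class MeaningPoint:
    """One force-flavor pair, the atomic communicable meaning."""

    force: str
    flavor: str

    def __repr__(self) -> str:  # compact, used in error messages and CSVs
        return f"({self.force},{self.flavor})"


def _unique_abbreviations(labels: Iterable[str]) -> dict[str, str]:
    """Shortest unique prefix per label, used as LoT atom names."""
    labels = list(labels)
    out = {}
    for lab in labels:
        for k in range(1, len(lab) + 1):
            prefix = lab[:k]
            if sum(1 for other in labels if other.startswith(prefix)) == 1:
                out[lab] = prefix
                break
        else:
            out[lab] = lab
    return out


@dataclass(frozen=True)
class MeaningSpace:
    """The full force x flavor grid, with a deterministic point order.

    Points are enumerated force-major (all flavors of the first force, then
    the second, ...), in declared label order, so every enumeration and
    serialization downstream is reproducible.
    """

    forces: tuple[str, ...]
    flavors: tuple[str, ...]

    def __post_init__(self) -> None:
        for axis, labels in (("force", self.forces), ("flavor", self.flavors)):
            if not labels:
                raise ValueError(f"empty {axis} label list")
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {axis} labels: {labels}")
        overlap = set(self.forces) & set(self.flavors)
        if overlap:
            raise ValueError(f"labels shared between axes: {sorted(overlap)}")
        pts = tuple(MeaningPoint(fo, fl) for fo in self.forces for fl in self.flavors)
        object.__setattr__(self, "_points", pts)
        object.__setattr__(self, "_index", {p: i for i, p in enumerate(pts)})

    @property
    def points(self) -> tuple[MeaningPoint, ...]:
        return self._points

    @property
    def size(self) -> int:
        return len(self._points)

    def index(self, p: MeaningPoint) -> int:
        try:
            return self._index[p]
        except KeyError:
            raise KeyError(f"point {p!r} not in space") from None

    def atom_names(self) -> dict[str, str]:
        """Short atom names for LoT formulas (shortest unique prefixes)."""
        return _unique_abbreviations(self.forces + self.flavors)

    # --- bitmask helpers (internal fast path used by search/evolution) ---

    def mask(self, points: Iterable[MeaningPoint]) -> int:
        m = 0
        for p in points:
            m |= 1 << self.index(p)
        return m

    def points_from_mask(self, mask: int) -> frozenset[MeaningPoint]:
        pts = self.points
        return frozenset(pts[i] for i in range(self.size) if mask >> i & 1)

    def meaning_from_mask(self, mask: int) -> "ModalMeaning":
        return ModalMeaning(self.points_from_mask(mask))


@dataclass(frozen=True)
class ModalMeaning:
    """The set of force-flavor pairs a modal can express (non-empty)."""

    points: frozenset[MeaningPoint]

    def __init__(self, points: Iterable[MeaningPoint]) -> None:
        object.__setattr__(self, "points", frozenset(points))
        if not self.points:
            raise ValueError("a modal meaning must contain at least one point")

    def forces(self) -> frozenset[str]:
        return frozenset(p.force for p in self.points)

    def flavors(self) -> frozenset[str]:
        return frozenset(p.flavor for p in self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __contains__(self, p: MeaningPoint) -> bool:
        return p in self.points

    def sort_key(self) -> tuple:
        return tuple(sorted((p.force, p.flavor) for p in self.points))

    def __repr__(self) -> str:
        pts = "+".join(f"{p.force}-{p.flavor}" for p in sorted(self.points))
        return f"ModalMeaning({pts})"


def build_space(forces: Iterable[str], flavors: Iterable[str]) -> MeaningSpace:
    """Construct a meaning space from force and flavor label lists."""
    return MeaningSpace(tuple(forces), tuple(flavors))


def default_space() -> MeaningSpace:
    """The 2-force x 3-flavor space used by the main analysis."""
    return build_space(DEFAULT_FORCES, DEFAULT_FLAVORS)


@functools.lru_cache(maxsize=None)
def _enumerated(space: MeaningSpace) -> tuple[ModalMeaning, ...]:
    return tuple(space.meaning_from_mask(m) for m in range(1, 1 << space.size))


def enumerate_meanings(space: MeaningSpace) -> list[ModalMeaning]:
    """All 2^n - 1 non-empty subsets of the space's points, in mask order."""
    return list(_enumerated(space))


def force_projection(m: ModalMeaning) -> frozenset[str]:
    """fo(m): the set of forces appearing in the meaning's points."""
    return m.forces()


def flavor_projection(m: ModalMeaning) -> frozenset[str]:
    """fl(m): the set of flavors appearing in the meaning's points."""
    return m.flavors()


class NeedDistribution:
    """A probability distribution over the meaning points of a space."""

    def __init__(self, space: MeaningSpace, prob: Mapping[MeaningPoint, float]):
        missing = set(space.points) - set(prob)
        if missing:
            raise ValueError(f"need distribution missing points: {sorted(missing)}")
        extra = set(prob) - set(space.points)
        if extra:
            raise ValueError(f"need distribution has unknown points: {sorted(extra)}")
        vals = {p: float(prob[p]) for p in space.points}
        if any(v < 0 for v in vals.values()):
            raise ValueError("negative probability in need distribution")
        total = sum(vals.values())
        if total <= 0:
            raise ValueError("need distribution sums to zero")
        if abs(total - 1.0) > 1e-9:
            vals = {p: v / total for p, v in vals.items()}
        self.space = space
        self.prob = vals

    def __getitem__(self, p: MeaningPoint) -> float:
        return self.prob[p]

    def as_array(self) -> np.ndarray:
        """Probabilities in the space's point order."""
        return np.array([self.prob[p] for p in self.space.points])

    def __repr__(self) -> str:
        return f"NeedDistribution({self.prob})"


def uniform_need(space: MeaningSpace) -> NeedDistribution:
    """Uniform communicative need over all points of the space."""
    q = 1.0 / space.size
    return NeedDistribution(space, {p: q for p in space.points})


def load_need(source, space: MeaningSpace) -> NeedDistribution:
    """Load a need distribution from a CSV with columns force, flavor, probability.

    Accepts a path or a DataFrame.  Every point of the space must appear
    exactly once; probabilities are normalized if they do not already sum to
    one within 1e-9 (so a table that sums exactly to 1 is preserved verbatim).
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    required = {"force", "flavor", "probability"}
    if not required <= set(df.columns):
        raise ValueError(f"need table must have columns {sorted(required)}")
    prob: dict[MeaningPoint, float] = {}
    for row in df.itertuples(index=False):
        p = MeaningPoint(str(row.force), str(row.flavor))
        if p in prob:
            raise ValueError(f"duplicate entry for point {p!r}")
        prob[p] = float(row.probability)
    return NeedDistribution(space, prob)


def estimated_need(space: MeaningSpace | None = None) -> NeedDistribution:
    """The packaged corpus-estimated need distribution over the 2x3 space.

    Relative frequencies of force-flavor pairs of English modal auxiliaries
    in an expert-annotated news corpus; used as the default prior for the
    main analysis.
    """
    if space is None:
        space = default_space()
    ref = resources.files("modals_effcomm").joinpath("data/need_gme.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return load_need(df, space)
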