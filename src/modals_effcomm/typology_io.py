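"""Reading and writing modal inventories.

The tabular input dialect has one row per (expression, force, flavor)
combination with a 0/1 ``can_express`` judgment; an expression's meaning is
the set of pairs judged expressible.  Pools of languages are serialized as
JSON lines for lossless round-trips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .meaning_space import MeaningPoint, MeaningSpace, ModalMeaning

__all__ = ["Language", "read_inventories", "remove_synonyms", "write_languages", "read_languages"]

logger = logging.getLogger(__name__)

PROVENANCES = ("natural", "sampled", "evolved", "synthetic")


@dataclass(frozen=True)
class Language:
    """A modal inventory: a named multiset of (expression, meaning) pairs."""

    name: str
    modals: tuple[tuple[str, ModalMeaning], ...]
    provenance: str = "natural"

    def __post_init__(self) -> None:
        if not self.modals:
            raise ValueError("a language must contain at least one modal")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def meanings(self) -> list[ModalMeaning]:
        return [m for _, m in self.modals]

    @property
    def size(self) -> int:
        return len(self.modals)

    def canonical_key(self) -> tuple:
        """Multiset-of-meanings identity, ignoring expression labels."""
        return tuple(sorted(m.sort_key() for m in self.meanings()))

    def __len__(self) -> int:
        return len(self.modals)


def read_inventories(path, space: MeaningSpace) -> list[Language]:
    """Read one or more modal inventories from a CSV/TSV judgment table.

    Expected columns: ``expression``, ``force``, ``flavor``, ``can_express``
    and, for multi-language files, ``language_name``.  Rows whose force or
    flavor is outside the active space are skipped with a warning (mirroring
    the restriction of the analysis to the covered grid); expressions with
    no positive judgment are dropped with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty inventory file: {path}")
    required = {"expression", "force", "flavor", "can_express"}
    if not required <= set(df.columns):
        raise ValueError(f"inventory file must have columns {sorted(required)}")
    if "language_name" not in df.columns:
        df = df.assign(language_name=path.stem)

    valid_points = set(space.points)
    languages: list[Language] = []
    for lang_name, group in df.groupby("language_name", sort=False):
        modals: list[tuple[str, ModalMeaning]] = []
        for expr, rows in group.groupby("expression", sort=False):
            points = []
            for row in rows.itertuples(index=False):
                flag = int(row.can_express)
                if flag not in (0, 1):
                    raise ValueError(
                        f"{lang_name}/{expr}: can_express must be 0 or 1, got {row.can_express!r}"
                    )
                p = MeaningPoint(str(row.force), str(row.flavor))
                if p not in valid_points:
                    logger.warning("%s/%s: point %r outside the active space, skipped", lang_name, expr, p)
                    continue
                if flag:
                    points.append(p)
            if points:
                modals.append((str(expr), ModalMeaning(points)))
            else:
                logger.warning("%s: expression %r has no expressible point, dropped", lang_name, expr)
        if modals:
            languages.append(Language(str(lang_name), tuple(modals), provenance="natural"))
        else:
            logger.warning("language %r has no usable modal, dropped", lang_name)
    return languages


def remove_synonyms(L: Language) -> Language:
    """Keep one representative per distinct meaning (first by expression label)."""
    seen: dict[frozenset, tuple[str, ModalMeaning]] = {}
    for expr, meaning in sorted(L.modals, key=lambda em: em[0]):
        if meaning.points not in seen:
            seen[meaning.points] = (expr, meaning)
    kept = tuple(sorted(seen.values(), key=lambda em: em[0]))
    return Language(L.name, kept, L.provenance)


def _language_to_record(L: Language) -> dict:
    return {
        "name": L.name,
        "provenance": L.provenance,
        "modals": [
            {"expression": expr, "points": sorted([p.force, p.flavor] for p in meaning.points)}
            for expr, meaning in L.modals
        ],
    }


def _language_from_record(rec: dict) -> Language:
    modals = tuple(
        (m["expression"], ModalMeaning(MeaningPoint(fo, fl) for fo, fl in m["points"]))
        for m in rec["modals"]
    )
    return Language(rec["name"], modals, rec.get("provenance", "natural"))


def write_languages(pool: Iterable[Language], path) -> None:
    """Serialize a pool of languages as JSON lines."""
    with open(path, "w") as fh:
        for L in pool:
            fh.write(json.dumps(_language_to_record(L), sort_keys=True) + "\n")


def read_languages(path) -> list[Language]:
    """Read a JSON-lines pool written by :func:`write_languages`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_language_from_record(json.loads(line)))
    return out
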