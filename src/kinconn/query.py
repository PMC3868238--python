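"""Query construction: direct kinase lists, kinase-family and GO-term expansion.

A query is a set of kinase symbols.  It can be typed directly, expanded
from one of the conserved-catalytic-domain kinase families (the human
kinome is conventionally split into seven such groups), or expanded from
a Gene Ontology biological-process term.  Family and GO annotation maps
are plain user-supplied TSV tables; a term's kinase set is exactly its
listed kinases (no ontology-graph propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "QuerySet",
    "AnnotationMap",
    "QueryError",
    "parse_query",
    "expand_family",
    "expand_go",
    "load_family_map",
    "load_go_map",
]


class QueryError(ValueError):
    """A query that cannot be resolved into at least one known kinase."""


def _norm(token: str) -> str:
    return str(token).strip().upper()


@dataclass(frozen=True)
class QuerySet:
    """Validated query kinase set.

    ``provenance`` is ``direct``, ``family`` or ``go``; ``selection``
    names the family or GO term when applicable.  ``unmatched_inputs``
    keeps tokens absent from the reference universe — reported, never
    silently dropped.
    """

    kinases: frozenset[str]
    provenance: str = "direct"
    selection: str | None = None
    unmatched_inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.kinases:
            raise QueryError("query set has no kinases")


@dataclass(frozen=True)
class AnnotationMap:
    """Kinase→family (one family per kinase) and kinase→GO-term tables."""

    family: dict[str, str] = field(default_factory=dict)
    go: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    # go: term id -> (term name, kinase set)

    def families(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for kinase, fam in self.family.items():
            out.setdefault(fam, set()).add(kinase)
        return {fam: frozenset(ks) for fam, ks in out.items()}


def parse_query(
    tokens: Iterable[str], universe: Iterable[str] | None = None
) -> QuerySet:
    """Build a direct QuerySet: uppercase, trim, deduplicate, and split
    against the reference kinase universe when one is given.

    Raises :class:`QueryError` when no token matches the universe.
    """
    cleaned = sorted({_norm(t) for t in tokens if _norm(t)})
    if not cleaned:
        raise QueryError("no query tokens given")
    if universe is None:
        return QuerySet(kinases=frozenset(cleaned))
    uni = {_norm(k) for k in universe}
    matched = [t for t in cleaned if t in uni]
    unmatched = tuple(t for t in cleaned if t not in uni)
    if not matched:
        raise QueryError(
            f"no query kinase found in the reference universe; "
            f"unmatched tokens: {list(unmatched)}"
        )
    return QuerySet(kinases=frozenset(matched), unmatched_inputs=unmatched)


def expand_family(family: str, annotation: AnnotationMap) -> QuerySet:
    """All kinases annotated to one kinase family (case-insensitive name)."""
    fams = annotation.families()
    lookup = {f.upper(): f for f in fams}
    key = _norm(family)
    if key not in lookup:
        raise QueryError(
            f"unknown kinase family {family!r}; available: {sorted(fams)}"
        )
    name = lookup[key]
    return QuerySet(
        kinases=fams[name], provenance="family", selection=name
    )


def expand_go(term: str, annotation: AnnotationMap) -> QuerySet:
    """Kinases of one GO biological-process term.

    ``term`` is either an exact term id (e.g. ``GO:0000165``) or a
    case-insensitive substring of a term name that resolves to exactly
    one term; an ambiguous substring raises listing the candidates.
    """
    key = str(term).strip()
    if key.upper() in {t.upper() for t in annotation.go}:
        tid = next(t for t in annotation.go if t.upper() == key.upper())
        name, kinases = annotation.go[tid]
        return QuerySet(kinases=kinases, provenance="go", selection=tid)
    hits = [
        (tid, name)
        for tid, (name, _) in annotation.go.items()
        if key.lower() in name.lower()
    ]
    if not hits:
        raise QueryError(
            f"GO term {term!r} not found by id or name substring"
        )
    if len(hits) > 1:
        raise QueryError(
            f"GO name substring {term!r} is ambiguous: "
            f"{[f'{t} ({n})' for t, n in sorted(hits)]}"
        )
    tid, _ = hits[0]
    return QuerySet(
        kinases=annotation.go[tid][1], provenance="go", selection=tid
    )


def load_family_map(path: str | Path) -> AnnotationMap:
    """Read a 2-column TSV ``kinase<TAB>family`` into an AnnotationMap."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["kinase", "family"], dtype=str)
    family = {
        _norm(row.kinase): str(row.family).strip()
        for row in df.itertuples()
    }
    return AnnotationMap(family=family)


def load_go_map(path: str | Path, base: AnnotationMap | None = None) -> AnnotationMap:
    """Read a 3-column TSV ``kinase<TAB>go_id<TAB>go_name``; merges into
    ``base`` when given so one map can carry both annotations."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["kinase", "go_id", "go_name"], dtype=str)
    go: dict[str, tuple[str, set[str]]] = {}
    for row in df.itertuples():
        tid = str(row.go_id).strip()
        name = str(row.go_name).strip()
        entry = go.setdefault(tid, (name, set()))
        entry[1].add(_norm(row.kinase))
    frozen = {tid: (name, frozenset(ks)) for tid, (name, ks) in go.items()}
    return AnnotationMap(
        family=dict(base.family) if base else {}, go=frozen
    )
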