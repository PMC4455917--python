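"""Signed gene-set ("mechanism") collections.

A mechanism is a named set of genes each tagged with the direction (+1 or
-1) in which its expression moves when the mechanism's upstream entity is
active.  Collections are read from a signed-GMT dialect (one set per line,
``name<TAB>description<TAB>gene:+1<TAB>gene:-1...``) or from a long-format
TSV (``name<TAB>gene<TAB>sign`` with a header row).

Gene identifiers are opaque strings; no identifier translation is
performed — callers supply IDs matched to their expression matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "SignedGeneSet",
    "MechanismCollection",
    "read_signed_gmt",
    "write_signed_gmt",
    "read_long_tsv",
    "resolve_conflicts",
    "filter_by_coverage",
]


class SignedGmtParseError(ValueError):
    """Raised for malformed signed-GMT / long-format input."""


@dataclass(frozen=True)
class SignedGeneSet:
    """A mechanism: genes mapped to a direction of regulation.

    Parameters
    ----------
    name : str
        Unique identifier within a collection.
    description : str
        Free-text annotation.
    members : dict
        Mapping gene-id -> sign, sign in {+1, -1}.  Insertion order is
        preserved and survives read/write round-trips.
    """

    name: str
    description: str
    members: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        bad = {g: s for g, s in self.members.items() if s not in (1, -1)}
        if bad:
            raise ValueError(f"gene set {self.name!r}: signs must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.members)

    def genes(self) -> list[str]:
        return list(self.members)

    def coverage(self, universe: set[str] | frozenset[str]) -> int:
        """Number of member genes present in ``universe``."""
        return sum(1 for g in self.members if g in universe)


@dataclass
class MechanismCollection:
    """Ordered collection of :class:`SignedGeneSet` with unique names."""

    sets: list[SignedGeneSet] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate mechanism names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> SignedGeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _parse_member_token(token: str, lineno: int) -> tuple[str, int]:
    gene, sep, sign = token.rpartition(":")
    if not sep or not gene:
        raise SignedGmtParseError(
            f"line {lineno}: member token {token!r} is not 'gene:+1' or 'gene:-1'"
        )
    if sign not in ("+1", "-1", "1"):
        raise SignedGmtParseError(
            f"line {lineno}: sign {sign!r} for gene {gene!r} not in {{+1, -1}}"
        )
    return gene, 1 if sign in ("+1", "1") else -1


def read_signed_gmt(path: str | Path, provenance: str | None = None) -> MechanismCollection:
    """Read a signed-GMT file.

    One set per non-blank line: ``name<TAB>description<TAB>gene:+1...``.
    Lines starting with ``#`` are ignored.  Duplicate set names raise.
    """
    path = Path(path)
    sets: list[SignedGeneSet] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SignedGmtParseError(
                    f"line {lineno}: expected name, description and >=1 member"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise SignedGmtParseError(f"line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            members: dict[str, int] = {}
            for token in fields[2:]:
                if not token:
                    continue
                gene, sign = _parse_member_token(token, lineno)
                if gene in members and members[gene] != sign:
                    raise SignedGmtParseError(
                        f"line {lineno}: gene {gene!r} listed with both signs"
                        " (use resolve_conflicts on long-format input)"
                    )
                members[gene] = sign
            if not members:
                raise SignedGmtParseError(f"line {lineno}: set {name!r} has no members")
            sets.append(SignedGeneSet(name, description, members))
    return MechanismCollection(sets, provenance=provenance or str(path))


def write_signed_gmt(coll: MechanismCollection, path: str | Path) -> None:
    """Write a collection in the signed-GMT dialect (inverse of read)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in coll:
            tokens = [f"{g}:{'+1' if sign > 0 else '-1'}" for g, sign in s.members.items()]
            fh.write("\t".join([s.name, s.description] + tokens) + "\n")


def read_long_tsv(path: str | Path, provenance: str | None = None) -> MechanismCollection:
    """Read the two-column long format: ``name<TAB>gene<TAB>sign`` with header.

    Duplicate and conflicting entries are resolved by :func:`resolve_conflicts`.
    """
    path = Path(path)
    triples: list[tuple[str, str, int]] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return MechanismCollection([], provenance=provenance or str(path))
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise SignedGmtParseError(f"line {lineno}: expected 3 columns")
            name, gene, sign_str = fields
            if sign_str not in ("+1", "-1", "1"):
                raise SignedGmtParseError(
                    f"line {lineno}: sign {sign_str!r} not in {{+1, -1}}"
                )
            triples.append((name, gene, 1 if sign_str in ("+1", "1") else -1))
    coll = resolve_conflicts(triples)
    coll.provenance = provenance or str(path)
    return coll


def resolve_conflicts(raw: Iterable[tuple[str, str, int]]) -> MechanismCollection:
    """Build a collection from (name, gene, sign) triples.

    Within a set, duplicate (gene, sign) pairs are deduplicated; a gene
    listed with both signs is dropped from that set with a warning.  Set
    order follows first appearance; member order likewise.
    """
    per_set: dict[str, dict[str, set[int]]] = {}
    for name, gene, sign in raw:
        per_set.setdefault(name, {}).setdefault(gene, set()).add(sign)
    sets = []
    for name, genes in per_set.items():
        members: dict[str, int] = {}
        for gene, signs in genes.items():
            if len(signs) > 1:
                logger.warning(
                    "mechanism %s: gene %s listed with both signs; dropped", name, gene
                )
                continue
            members[gene] = next(iter(signs))
        if members:
            sets.append(SignedGeneSet(name, "", members))
        else:
            logger.warning("mechanism %s: no members after conflict resolution", name)
    return MechanismCollection(sets)


def filter_by_coverage(
    coll: MechanismCollection,
    gene_universes: list[set[str]],
    min_genes: int = 4,
) -> MechanismCollection:
    """Keep sets with at least ``min_genes`` members measured in EVERY universe.

    Mirrors restricting the knowledge base to mechanisms with at least four
    genes measured on every cohort's platform.  Original order is preserved.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if not gene_universes:
        raise ValueError("at least one gene universe required")
    universes = [frozenset(u) for u in gene_universes]
    kept = [
        s for s in coll
        if all(s.coverage(u) >= min_genes for u in universes)
    ]
    return MechanismCollection(kept, provenance=coll.provenance)
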