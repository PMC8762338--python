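"""Gene-set collections: GMT input/output and restriction to a measured gene space.

Gene identifiers are matched case-insensitively after whitespace trimming,
because marker lists and expression platforms rarely agree on symbol casing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from .containers import ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValueError("gene set name must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        """Build a set, normalizing symbols and dropping duplicates (order kept)."""
        seen: dict[str, None] = {}
        n_raw = 0
        for g in genes:
            n_raw += 1
            sym = normalize_symbol(g)
            if sym and sym not in seen:
                seen[sym] = None
        if n_raw != len(seen):
            logger.warning("gene set %r: %d duplicate/empty gene entries removed",
                           name, n_raw - len(seen))
        return cls(name=str(name).strip(), genes=tuple(seen), description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes

    def intersect(self, genes: Iterable[str]) -> tuple[str, ...]:
        pool = {normalize_symbol(g) for g in genes}
        return tuple(g for g in self.genes if g in pool)


@dataclass
class GeneSetCollection:
    """Mapping of set name to :class:`GeneSet` with provenance.

    ``restriction`` records, after :func:`restrict_to_matrix`, the original
    and retained size of each surviving set.
    """

    sets: dict[str, GeneSet]
    source: str = ""
    restriction: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene set collection must be non-empty")
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"collection key {name!r} does not match set name {gs.name!r}")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet], source: str = "") -> "GeneSetCollection":
        mapping: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in mapping:
                raise ValueError(f"duplicate gene set name {gs.name!r}")
            mapping[gs.name] = gs
        return cls(sets=mapping, source=source)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: ``name TAB description TAB gene...``.

    Comment lines starting with ``#`` and blank lines are skipped. Duplicate
    genes within a line are removed with a warning; duplicate set names and
    lines with fewer than three fields are errors.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line "
                    f"(expected >=3 tab-separated fields, got {len(fields)})")
            name, description, *genes = fields
            gs = GeneSet.from_genes(name, genes, description=description)
            if gs.name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene set name {gs.name!r}")
            sets[gs.name] = gs
    if not sets:
        raise ValueError(f"{path.name}: no gene sets found")
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    """Write a collection as GMT; round-trips names and memberships exactly."""
    if len(collection) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("cannot write an empty collection")
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            for token in (gs.name, gs.description, *gs.genes):
                if "\t" in token or "\n" in token:
                    raise ValueError(
                        f"gene set {gs.name!r}: field {token!r} contains a tab/newline, "
                        "which the GMT format cannot represent")
            fh.write("\t".join((gs.name, gs.description, *gs.genes)) + "\n")


def restrict_to_matrix(collection: GeneSetCollection, matrix: ExpressionMatrix,
                       min_fraction: float = 0.5, min_genes: int = 2) -> GeneSetCollection:
    """Intersect every set with the matrix's genes; drop poorly covered sets.

    A set is kept only if it retains at least ``min_fraction`` of its genes
    and at least ``min_genes`` genes (an enrichment score over fewer than two
    genes is not meaningful). Idempotent. Retained sizes are recorded in
    ``restriction``.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if matrix.n_genes < 1:
        raise ValueError("matrix must contain at least one gene")
    measured = set(matrix.genes)
    kept: dict[str, GeneSet] = {}
    restriction: dict[str, tuple[int, int]] = {}
    for gs in collection:
        retained = tuple(g for g in gs.genes if g in measured)
        if len(retained) < min_genes or len(retained) < min_fraction * len(gs.genes):
            logger.warning("dropping gene set %r: %d/%d genes measured",
                           gs.name, len(retained), len(gs.genes))
            continue
        kept[gs.name] = GeneSet(name=gs.name, genes=retained, description=gs.description)
        restriction[gs.name] = (len(gs.genes), len(retained))
    if not kept:
        raise ValueError("no usable gene sets after restriction to the expression matrix")
    out = GeneSetCollection(sets=kept, source=collection.source)
    out.restriction = restriction
    return out
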