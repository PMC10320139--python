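"""Domain model: genes, chromosomes, family sequences, tracks, data sources.

Every computation in this package operates on ordered lists of gene-family
identifiers ("family sequences"), the common currency that lets independently
loaded data sources be searched and compared transparently.  Coordinates are
0-based half-open internally; GFF3 I/O converts to/from 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence


class SyntenicError(Exception):
    """Base class for errors raised by this package."""


class NotFoundError(SyntenicError):
    """A named gene or chromosome does not exist in the given data source."""


def gene_sort_key(gene: "Gene") -> tuple:
    # Order by start; ties (overlapping genes) broken by end then name so the
    # gene order of a chromosome is total and reproducible.
    return (gene.start, gene.end, gene.name)


@dataclass(frozen=True)
class Gene:
    """A located, stranded, family-annotated annotation unit.

    ``family is None`` marks an orphan gene: a gene with no functional
    annotation, which matches nothing in any comparison.
    """

    name: str
    chromosome: str
    start: int
    end: int
    strand: int
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.name}: start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.name}: end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.name}: strand must be +1 or -1, got {self.strand}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_orphan(self) -> bool:
        return self.family is None


@dataclass
class Chromosome:
    """A named, ordered run of genes belonging to one genome."""

    name: str
    genome: str
    length: int
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=gene_sort_key)
        for g in self.genes:
            if g.chromosome != self.name:
                raise ValueError(
                    f"gene {g.name} claims chromosome {g.chromosome!r}, "
                    f"placed on {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def family_sequence(self) -> "FamilySequence":
        return FamilySequence.from_genes(self.genes)


# A symbol is a (family-or-None, strand) pair.
Symbol = tuple[Optional[str], int]


@dataclass(frozen=True)
class FamilySequence:
    """Ordered (family, strand) symbols derived from a chromosome or track.

    Orphan genes appear as ``None`` families.  An orphan symbol is never equal
    to any other symbol, including another orphan: each unannotated gene is a
    distinct anonymous identity.
    """

    symbols: tuple[Symbol, ...]

    @classmethod
    def from_genes(cls, genes: Sequence[Gene]) -> "FamilySequence":
        return cls(tuple((g.family, g.strand) for g in genes))

    @classmethod
    def from_families(
        cls, families: Iterable[Optional[str]], strand: int = 1
    ) -> "FamilySequence":
        return cls(tuple((f, strand) for f in families))

    @property
    def families(self) -> tuple[Optional[str], ...]:
        return tuple(f for f, _ in self.symbols)

    def reversed(self) -> "FamilySequence":
        """Reverse gene order and flip strands (a full-sequence inversion)."""
        return FamilySequence(tuple((f, -s) for f, s in reversed(self.symbols)))

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i: int) -> Symbol:
        return self.symbols[i]

    def __iter__(self) -> Iterator[Symbol]:
        return iter(self.symbols)


def families_match(a: Optional[str], b: Optional[str]) -> bool:
    """Symbol equality at family resolution; orphans match nothing."""
    return a is not None and a == b


@dataclass
class Track:
    """A contiguous slice of one chromosome's gene order.

    ``first``/``last`` are inclusive gene indices into the chromosome;
    ``query_gene_index`` (when set) is the focal gene's offset *within* the
    track.
    """

    source: str
    chromosome: str
    first: int
    last: int
    genes: list[Gene]
    query_gene_index: Optional[int] = None
    is_query: bool = False

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise ValueError(f"track span [{self.first}, {self.last}] is empty")
        if len(self.genes) != self.last - self.first + 1:
            raise ValueError(
                f"track on {self.chromosome}: {len(self.genes)} genes do not fill "
                f"span [{self.first}, {self.last}]"
            )
        if self.query_gene_index is not None and not (
            0 <= self.query_gene_index < len(self.genes)
        ):
            raise ValueError("query_gene_index outside track")

    @property
    def span(self) -> tuple[int, int]:
        return (self.first, self.last)

    def __len__(self) -> int:
        return len(self.genes)

    def family_sequence(self) -> FamilySequence:
        return FamilySequence.from_genes(self.genes)


@dataclass
class DataSource:
    """One loaded genome database: chromosomes plus an inverted family index.

    ``family_index`` maps each non-orphan family to the ordered list of
    (chromosome name, gene index) occurrences.  Multiple sources sharing a
    family vocabulary compose transparently: all cross-source computation
    happens through family sequences.
    """

    name: str
    chromosomes: dict[str, Chromosome]
    family_index: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.family_index:
            self.family_index = build_family_index(self.chromosomes)

    def gene_location(self, gene_name: str) -> tuple[str, int]:
        """(chromosome name, gene index) of a gene; raises NotFoundError."""
        for chrom in self.chromosomes.values():
            for i, g in enumerate(chrom.genes):
                if g.name == gene_name:
                    return chrom.name, i
        raise NotFoundError(f"gene {gene_name!r} not found in source {self.name!r}")

    def family_count(self, family: str) -> int:
        return len(self.family_index.get(family, ()))

    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes.values())


def build_family_index(
    chromosomes: dict[str, Chromosome]
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for cname in sorted(chromosomes):
        for i, g in enumerate(chromosomes[cname].genes):
            if g.family is not None:
                index.setdefault(g.family, []).append((cname, i))
    return index


def build_data_source(
    chromosomes: Iterable[Chromosome],
    family_map: dict[str, Optional[str]],
    name: str,
) -> DataSource:
    """Attach family assignments to genes and build the inverted index.

    Genes absent from ``family_map`` (or mapped to None) become orphans.
    Gene names must be unique across the whole source.
    """
    seen: set[str] = set()
    out: dict[str, Chromosome] = {}
    for chrom in chromosomes:
        genes = []
        for g in chrom.genes:
            if g.name in seen:
                raise SyntenicError(f"duplicate gene name {g.name!r} in source {name!r}")
            seen.add(g.name)
            genes.append(replace(g, family=family_map.get(g.name)))
        out[chrom.name] = Chromosome(
            name=chrom.name, genome=chrom.genome, length=chrom.length, genes=genes
        )
    return DataSource(name=name, chromosomes=out)
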