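"""Shared test helpers: compact construction of sources and sequences."""

from __future__ import annotations

from typing import Optional, Sequence

from syntenic.model import (
    Chromosome,
    DataSource,
    FamilySequence,
    Gene,
    build_data_source,
)


def seq(families: Sequence[Optional[str]], strand: int = 1) -> FamilySequence:
    """FamilySequence from an iterable of family letters; None = orphan."""
    return FamilySequence.from_families(list(families), strand)


def seq_str(s: str) -> FamilySequence:
    """FamilySequence from a string, one family per character; '.' = orphan."""
    return FamilySequence.from_families([None if c == "." else c for c in s])


def source_from_families(
    name: str, chrom_families: dict[str, str], gene_length: int = 500, spacing: int = 1000
) -> DataSource:
    """DataSource with one gene per character; '.' characters are orphans."""
    chromosomes = []
    family_map = {}
    for cname, fams in chrom_families.items():
        genes = []
        for i, c in enumerate(fams):
            gname = f"{name}_{cname}_g{i}"
            genes.append(
                Gene(
                    name=gname,
                    chromosome=cname,
                    start=i * spacing,
                    end=i * spacing + gene_length,
                    strand=1 if i % 2 == 0 else -1,
                )
            )
            family_map[gname] = None if c == "." else c
        chromosomes.append(
            Chromosome(
                name=cname,
                genome=name,
                length=len(fams) * spacing,
                genes=genes,
            )
        )
    return build_data_source(chromosomes, family_map, name)
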