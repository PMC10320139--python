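"""Readers and writers: GFF3 gene annotations and gene->family TSV files.

External coordinates follow the GFF3 convention (1-based, inclusive); they are
converted to the package's internal 0-based half-open representation on read
and back on write.  The writer emits a fixed dialect (sorted chromosomes,
``##sequence-region`` pragmas, ID+Name attributes) so write->read->write is
byte-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, TextIO, Union

import gffutils.feature

from .model import Chromosome, DataSource, Gene, SyntenicError

logger = logging.getLogger(__name__)


class ParseError(SyntenicError):
    """A malformed input file; message carries the file and line number."""


def read_gff3(
    path: Union[str, Path],
    gene_feature_type: str = "gene",
    genome: Optional[str] = None,
) -> list[Chromosome]:
    """Read features of one type from a GFF3 file into Chromosome objects.

    Chromosome length comes from the ``##sequence-region`` pragma when
    present, else the maximum gene end.  Features must carry an ID attribute;
    strand "." is accepted as +1 with a logged warning.
    """
    path = Path(path)
    if genome is None:
        genome = path.stem.split(".")[0]
    region_lengths: dict[str, int] = {}
    genes_by_chrom: dict[str, list[Gene]] = {}
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        region_lengths[parts[1]] = int(parts[3])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: bad ##sequence-region pragma"
                        ) from None
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils is lenient
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != gene_feature_type:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            ids = feat.attributes.get("ID")
            if not ids:
                raise ParseError(f"{path}:{lineno}: {gene_feature_type} lacks ID attribute")
            gene_id = ids[0]
            if gene_id in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen_ids.add(gene_id)
            if feat.strand == "+":
                strand = 1
            elif feat.strand == "-":
                strand = -1
            else:
                logger.warning(
                    "%s:%d: gene %s has strand %r; assuming +",
                    path, lineno, gene_id, feat.strand,
                )
                strand = 1
            genes_by_chrom.setdefault(feat.seqid, []).append(
                Gene(
                    name=gene_id,
                    chromosome=feat.seqid,
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                )
            )
    chromosomes = []
    for cname in sorted(genes_by_chrom):
        genes = genes_by_chrom[cname]
        length = region_lengths.get(cname, max(g.end for g in genes))
        chromosomes.append(
            Chromosome(name=cname, genome=genome, length=length, genes=genes)
        )
    return chromosomes


def write_gff3(chromosomes: list[Chromosome], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        _write_gff3(chromosomes, fh)


def _write_gff3(chromosomes: list[Chromosome], fh: TextIO) -> None:
    fh.write("##gff-version 3\n")
    for chrom in sorted(chromosomes, key=lambda c: c.name):
        fh.write(f"##sequence-region {chrom.name} 1 {chrom.length}\n")
    for chrom in sorted(chromosomes, key=lambda c: c.name):
        for g in chrom.genes:
            strand = "+" if g.strand == 1 else "-"
            fh.write(
                f"{chrom.name}\tsyntenic\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.name};Name={g.name}\n"
            )


def read_family_tsv(path: Union[str, Path]) -> dict[str, Optional[str]]:
    """Read a gene<TAB>family assignment file.

    Columns beyond the second are ignored (assignment files often carry
    scores).  A blank family field means orphan.  A gene assigned two
    different families is an error.
    """
    path = Path(path)
    assignments: dict[str, Optional[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            gene, family = cols[0], cols[1].strip() or None
            if gene in assignments and assignments[gene] != family:
                raise SyntenicError(
                    f"{path}: gene {gene!r} assigned two families "
                    f"({assignments[gene]!r} and {family!r})"
                )
            assignments[gene] = family
    return assignments


def write_family_tsv(source: DataSource, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for cname in sorted(source.chromosomes):
            for g in source.chromosomes[cname].genes:
                if g.family is not None:
                    fh.write(f"{g.name}\t{g.family}\n")


def load_source(
    gff3_path: Union[str, Path],
    families_path: Union[str, Path],
    name: str,
    gene_feature_type: str = "gene",
) -> DataSource:
    """Convenience loader: GFF3 + family TSV -> DataSource."""
    from .model import build_data_source

    chromosomes = read_gff3(gff3_path, gene_feature_type, genome=name)
    family_map = read_family_tsv(families_path)
    return build_data_source(chromosomes, family_map, name)
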