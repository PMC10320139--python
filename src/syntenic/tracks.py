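"""Query-track construction: a focal gene plus flanking neighbors, or a
chromosome interval from which the focal gene and flank size are inferred."""

from __future__ import annotations

from .model import DataSource, NotFoundError, SyntenicError, Track


def make_query_track(source: DataSource, gene_name: str, neighbors: int) -> Track:
    """Build the track of up to ``neighbors`` genes either side of a gene.

    The track is truncated at chromosome ends, so its length is at most
    ``2 * neighbors + 1``.
    """
    if neighbors < 0:
        raise ValueError("neighbors must be >= 0")
    cname, idx = source.gene_location(gene_name)
    chrom = source.chromosomes[cname]
    first = max(0, idx - neighbors)
    last = min(len(chrom) - 1, idx + neighbors)
    return Track(
        source=source.name,
        chromosome=cname,
        first=first,
        last=last,
        genes=list(chrom.genes[first : last + 1]),
        query_gene_index=idx - first,
        is_query=True,
    )


def make_track_from_interval(
    source: DataSource, chromosome_name: str, start_bp: int, end_bp: int
) -> Track:
    """Infer a (query gene, neighbors) track from a base-pair interval.

    The query gene is the overlapping gene whose midpoint is nearest the
    interval midpoint (ties -> leftmost); neighbors is the smallest flank that
    covers every overlapping gene.  The derived track may extend beyond the
    interval on one side when the overlap is asymmetric around the query gene.
    """
    if end_bp <= start_bp:
        raise ValueError("interval end must be > start")
    chrom = source.chromosomes.get(chromosome_name)
    if chrom is None:
        raise NotFoundError(
            f"chromosome {chromosome_name!r} not found in source {source.name!r}"
        )
    overlapping = [
        i for i, g in enumerate(chrom.genes) if g.start < end_bp and g.end > start_bp
    ]
    if not overlapping:
        raise SyntenicError(
            f"no genes overlap {chromosome_name}:[{start_bp}, {end_bp}) "
            f"in source {source.name!r}"
        )
    mid = (start_bp + end_bp) / 2.0
    qi = min(overlapping, key=lambda i: (abs(chrom.genes[i].midpoint - mid), i))
    neighbors = max(qi - overlapping[0], overlapping[-1] - qi)
    first = max(0, qi - neighbors)
    last = min(len(chrom) - 1, qi + neighbors)
    return Track(
        source=source.name,
        chromosome=chromosome_name,
        first=first,
        last=last,
        genes=list(chrom.genes[first : last + 1]),
        query_gene_index=qi - first,
        is_query=True,
    )
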