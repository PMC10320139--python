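"""Microsynteny search: find chromosome segments whose gene-family content is
similar to a query family set.

The search is a fixed-radius near-neighbors problem over family content,
solved with a gaps-and-islands scan: an *island* is a maximal run of genes
whose families are in the query set, in which consecutive matching genes are
separated by at most ``intermediate`` non-matching genes; islands with fewer
than ``matched`` matching genes are discarded.  Orphan genes always count as
non-matching intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import DataSource, FamilySequence, Track


@dataclass
class SearchParams:
    """Feasibility radius of the search.

    matched: minimum matching genes per island (>= 1).
    intermediate: maximum consecutive non-matching genes inside an island.
    mask_threshold: families occurring more often than this genome-wide in the
        searched source are excluded from the query set (None = no masking).
    matched_distinct: count distinct matching families instead of matching
        genes when applying the ``matched`` cutoff.
    """

    matched: int = 4
    intermediate: int = 5
    mask_threshold: Optional[int] = None
    matched_distinct: bool = False

    def __post_init__(self) -> None:
        if self.matched < 1:
            raise ValueError("matched must be >= 1")
        if self.intermediate < 0:
            raise ValueError("intermediate must be >= 0")


@dataclass
class SearchHit:
    track: Track
    matched_count: int
    coverage: float


def query_family_set(
    tracks: list[Track],
    mask_threshold: Optional[int] = None,
    source: Optional[DataSource] = None,
) -> set[str]:
    """Union of non-orphan families over the query tracks.

    With a mask threshold and a source, families whose genome-wide occurrence
    count in that source exceeds the threshold are excluded (masking of
    promiscuous families).
    """
    fams: set[str] = set()
    for t in tracks:
        fams.update(f for f in t.family_sequence().families if f is not None)
    if mask_threshold is not None and source is not None:
        fams = {f for f in fams if source.family_count(f) <= mask_threshold}
    return fams


def find_islands(
    sequence: FamilySequence, families: set[str], params: SearchParams
) -> list[tuple[int, int, int]]:
    """Gaps-and-islands scan of one chromosome's family sequence.

    Returns disjoint, left-to-right (first_index, last_index, matched_count)
    triples, trimmed to begin and end on matching genes.
    """
    match_positions = [
        i for i, (fam, _) in enumerate(sequence) if fam is not None and fam in families
    ]
    islands: list[tuple[int, int, int]] = []
    run: list[int] = []
    for pos in match_positions:
        if run and pos - run[-1] - 1 > params.intermediate:
            islands.append(_close(run, sequence, params))
            run = []
        run.append(pos)
    if run:
        islands.append(_close(run, sequence, params))
    return [isl for isl in islands if isl[2] >= params.matched]


def _close(
    run: list[int], sequence: FamilySequence, params: SearchParams
) -> tuple[int, int, int]:
    if params.matched_distinct:
        count = len({sequence[i][0] for i in run})
    else:
        count = len(run)
    return (run[0], run[-1], count)


def search(
    sources: list[DataSource], query_tracks: list[Track], params: SearchParams
) -> list[SearchHit]:
    """Search every chromosome of every source for islands of query families.

    Self-hits (the query regions re-found on their own chromosomes) are
    returned like any other hit; suppressing them is a display decision.
    Results are sorted by (source, chromosome, start).  Sources are searched
    independently, so the result over [S1, S2] is the union of per-source
    results.
    """
    if not query_tracks:
        raise ValueError("at least one query track is required")
    hits: list[SearchHit] = []
    for source in sources:
        fams = query_family_set(query_tracks, params.mask_threshold, source)
        if not fams:
            continue
        denom = len(fams)
        for cname in sorted(source.chromosomes):
            chrom = source.chromosomes[cname]
            for first, last, count in find_islands(
                chrom.family_sequence(), fams, params
            ):
                track = Track(
                    source=source.name,
                    chromosome=cname,
                    first=first,
                    last=last,
                    genes=list(chrom.genes[first : last + 1]),
                )
                hits.append(
                    SearchHit(track=track, matched_count=count, coverage=count / denom)
                )
    hits.sort(key=lambda h: (h.track.source, h.track.chromosome, h.track.first))
    return hits
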