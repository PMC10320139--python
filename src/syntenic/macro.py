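"""Chromosome-scale synteny blocks, computed on demand from family-annotated
gene orders.

Blocks are chains of gene pairs that share a family, monotone on both
chromosomes (increasing target index for FORWARD blocks, decreasing for
INVERTED), with per-step gaps bounded by ``intermediate`` gene-index units on
either chromosome — a simplified collinearity chaining in the MCScanX family,
with family membership standing in for sequence homology.  Target chromosomes
are ordered for display by an inversion-aware 2-mer multiset Jaccard distance
to the query chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import Orientation, greedy_interval_rows
from .model import Chromosome, DataSource, FamilySequence, NotFoundError


@dataclass
class MacroParams:
    """matched: minimum gene pairs per block (>= 2, since orientation is
    defined by the first two chain members); intermediate: maximum gap in
    gene-index units between chained pairs, on either chromosome;
    mask_threshold: families with more combined occurrences than this on the
    two chromosomes being compared contribute no pairs (None = no masking)."""

    matched: int = 10
    intermediate: int = 10
    mask_threshold: Optional[int] = 10

    def __post_init__(self) -> None:
        if self.matched < 2:
            raise ValueError("matched must be >= 2")
        if self.intermediate < 0:
            raise ValueError("intermediate must be >= 0")


@dataclass
class SyntenyBlock:
    query_chromosome: str
    target_chromosome: str
    query_span: tuple[int, int]   # gene-index, inclusive
    target_span: tuple[int, int]
    orientation: Orientation
    pair_count: int
    query_bp: Optional[tuple[int, int]] = None
    target_bp: Optional[tuple[int, int]] = None
    target_source: Optional[str] = None
    target_genome: Optional[str] = None
    row: int = -1


def match_pairs(
    qc: FamilySequence, tc: FamilySequence, mask_threshold: Optional[int] = None
) -> list[tuple[int, int]]:
    """All (query index, target index) pairs sharing a non-orphan family.

    Masking counts a family's occurrences summed over the two chromosomes
    being compared; families exceeding the threshold contribute no pairs.
    """
    qf, tf = qc.families, tc.families
    occur: Counter = Counter(f for f in qf if f is not None)
    occur.update(f for f in tf if f is not None)
    by_family: dict[str, list[int]] = {}
    for j, f in enumerate(tf):
        if f is None:
            continue
        if mask_threshold is not None and occur[f] > mask_threshold:
            continue
        by_family.setdefault(f, []).append(j)
    pairs = [
        (i, j)
        for i, f in enumerate(qf)
        if f is not None
        for j in by_family.get(f, ())
    ]
    pairs.sort()
    return pairs


def chain_blocks(
    pairs: Sequence[tuple[int, int]],
    params: MacroParams,
    query_chromosome: Optional[Chromosome] = None,
    target_chromosome: Optional[Chromosome] = None,
) -> list[SyntenyBlock]:
    """Greedy seeded chaining of matched pairs into collinear blocks.

    Pairs are visited in (query, target) order; each unused pair seeds a
    chain that repeatedly absorbs the eligible next pair — strictly greater
    query index, gap at most ``intermediate`` on both axes, target index
    moving monotonically in the chain's orientation (fixed by its first two
    members) — preferring the smallest query index, then the smallest target
    jump.  Chains with at least ``matched`` pairs become blocks; each pair
    belongs to at most one block.
    """
    plist = sorted(pairs)
    n = len(plist)
    used = [False] * n
    blocks: list[SyntenyBlock] = []
    for seed in range(n):
        if used[seed]:
            continue
        chain = [seed]
        in_chain = {seed}
        direction = 0
        while True:
            q0, t0 = plist[chain[-1]]
            best_k, best_key, best_dt = -1, None, 0
            for k in range(chain[-1] + 1, n):
                q1, t1 = plist[k]
                if q1 <= q0:
                    continue
                if q1 - q0 - 1 > params.intermediate:
                    break  # plist sorted by query: no later pair can qualify
                if used[k] or k in in_chain:
                    continue
                dt = t1 - t0
                if dt == 0:
                    continue
                if direction != 0 and (dt > 0) != (direction > 0):
                    continue
                if abs(dt) - 1 > params.intermediate:
                    continue
                key = (q1, abs(dt), t1)
                if best_key is None or key < best_key:
                    best_k, best_key, best_dt = k, key, dt
            if best_k < 0:
                break
            chain.append(best_k)
            in_chain.add(best_k)
            if direction == 0:
                direction = 1 if best_dt > 0 else -1
        if len(chain) >= params.matched:
            for k in chain:
                used[k] = True
            qs = [plist[k][0] for k in chain]
            ts = [plist[k][1] for k in chain]
            block = SyntenyBlock(
                query_chromosome=query_chromosome.name if query_chromosome else "",
                target_chromosome=target_chromosome.name if target_chromosome else "",
                query_span=(min(qs), max(qs)),
                target_span=(min(ts), max(ts)),
                orientation=Orientation.FORWARD if direction > 0 else Orientation.INVERTED,
                pair_count=len(chain),
            )
            if query_chromosome is not None:
                genes = query_chromosome.genes
                block.query_bp = (genes[min(qs)].start, genes[max(qs)].end)
            if target_chromosome is not None:
                genes = target_chromosome.genes
                block.target_bp = (genes[min(ts)].start, genes[max(ts)].end)
                block.target_genome = target_chromosome.genome
            blocks.append(block)
    blocks.sort(key=lambda b: (b.query_span, b.target_span))
    return blocks


def jaccard_2mer_distance(a: FamilySequence, b: FamilySequence) -> float:
    """1 - Jaccard similarity of canonicalized adjacent family 2-mer multisets.

    Each adjacent pair of non-orphan families contributes its lexicographically
    canonical ordering, so the distance is invariant to full-sequence reversal
    ("supports inversions").  Two sequences with no 2-mers are at distance 0.
    """
    ca, cb = _canonical_2mers(a), _canonical_2mers(b)
    union = ca | cb
    if not union:
        return 0.0
    inter = ca & cb
    return 1.0 - sum(inter.values()) / sum(union.values())


def _canonical_2mers(seq: FamilySequence) -> Counter:
    fams = seq.families
    out: Counter = Counter()
    for f, g in zip(fams, fams[1:]):
        if f is None or g is None:
            continue
        out[(f, g) if f <= g else (g, f)] += 1
    return out


def order_chromosomes(
    query_chromosome: Chromosome,
    targets: Sequence[tuple[str, Chromosome]],
) -> list[tuple[float, str, Chromosome]]:
    """Sort (source, chromosome) targets by ascending 2-mer Jaccard distance
    to the query chromosome; ties by (source, name)."""
    qseq = query_chromosome.family_sequence()
    keyed = [
        (jaccard_2mer_distance(qseq, c.family_sequence()), src, c)
        for src, c in targets
    ]
    keyed.sort(key=lambda x: (x[0], x[1], x[2].name))
    return keyed


@dataclass
class MacroTrack:
    source: str
    chromosome: str
    genome: str
    distance: float
    blocks: list[SyntenyBlock]


def macrosynteny_tracks(
    query_chromosome: Chromosome,
    sources: Sequence[DataSource],
    params: MacroParams,
) -> list[MacroTrack]:
    """Blocks of every chromosome of every source against the query
    chromosome, ordered by syntenic distance, with per-chromosome display
    rows assigned by greedy interval scheduling on the query axis."""
    qseq = query_chromosome.family_sequence()
    targets = [
        (src.name, src.chromosomes[cname])
        for src in sources
        for cname in sorted(src.chromosomes)
    ]
    out: list[MacroTrack] = []
    for dist, src_name, chrom in order_chromosomes(query_chromosome, targets):
        pairs = match_pairs(qseq, chrom.family_sequence(), params.mask_threshold)
        blocks = chain_blocks(pairs, params, query_chromosome, chrom)
        for b in blocks:
            b.target_source = src_name
        if blocks:
            rows = greedy_interval_rows([b.query_span for b in blocks])
            for b, r in zip(blocks, rows):
                b.row = r
        out.append(
            MacroTrack(
                source=src_name,
                chromosome=chrom.name,
                genome=chrom.genome,
                distance=dist,
                blocks=blocks,
            )
        )
    return out


def circos_pairs(
    chromosomes: Sequence[tuple[str, Chromosome]], params: MacroParams
) -> dict:
    """All-pairs blocks among chromosomes, as Circos-style plot data.

    Returns chromosome entries (source, name, genome, base-pair length) and
    one entry per unordered pair with its block list (possibly empty).
    """
    if len(chromosomes) < 2:
        raise ValueError("circos requires at least 2 chromosomes")
    chrom_entries = [
        {"source": src, "name": c.name, "genome": c.genome, "length": c.length}
        for src, c in chromosomes
    ]
    pair_entries = []
    for i in range(len(chromosomes)):
        for j in range(i + 1, len(chromosomes)):
            src_a, a = chromosomes[i]
            src_b, b = chromosomes[j]
            blocks = chain_blocks(
                match_pairs(
                    a.family_sequence(), b.family_sequence(), params.mask_threshold
                ),
                params,
                a,
                b,
            )
            for blk in blocks:
                blk.target_source = src_b
            pair_entries.append(
                {
                    "a": {"source": src_a, "chromosome": a.name},
                    "b": {"source": src_b, "chromosome": b.name},
                    "blocks": blocks,
                }
            )
    return {"chromosomes": chrom_entries, "pairs": pair_entries}
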