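"""Gene-order local alignment of result tracks against a query or consensus.

Alignment operates on family sequences: two genes are equal iff they carry
the same (non-orphan) family identifier.  Strand never enters symbol
equality; orientation is a segment-level property discovered by aligning the
query against the reversed target and selecting a maximum-weight set of
non-overlapping forward and inverted segments with weighted interval
scheduling.

Three dynamic programs live here:

* ``smith_waterman`` -- the classical best single local alignment.
* ``repeat_align`` -- the repeated-matches DP (Durbin et al.): multiple
  local matches of the query in the target, disjoint in target coordinates,
  each worth at least ``repeat_T``.
* ``weighted_interval_schedule`` -- exact maximum-weight non-overlapping
  interval selection (sort + binary search).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .model import FamilySequence, Track, families_match

NEG_INF = float("-inf")

#: Minimum MATCH steps for an inverted segment; a single-gene "inversion" is a
#: strand flip, not a structural inversion.
MIN_INVERTED_MATCHES = 2


class Orientation(str, Enum):
    FORWARD = "forward"
    INVERTED = "inverted"


class StepState(str, Enum):
    MATCH = "match"
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"  # gene present in target but not query
    DELETION = "deletion"    # query gene absent from target


@dataclass(frozen=True)
class Step:
    query: Optional[int]
    target: Optional[int]
    state: StepState


@dataclass
class ScoringScheme:
    """Family-level matches are near-binary evidence of homology, hence the
    heavy match weight and light substitution/indel penalties."""

    match: float = 10.0
    mismatch: float = -1.0
    gap: float = -1.0
    score_threshold: float = 30.0
    repeat_T: float = 10.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be <= 0")
        if self.score_threshold < 0 or self.repeat_T < 0:
            raise ValueError("thresholds must be >= 0")

    def step_score(self, state: StepState) -> float:
        if state is StepState.MATCH:
            return self.match
        if state is StepState.SUBSTITUTION:
            return self.mismatch
        return self.gap


@dataclass
class AlignmentSegment:
    orientation: Orientation
    steps: list[Step]
    score: float

    @property
    def n_matches(self) -> int:
        return sum(1 for s in self.steps if s.state is StepState.MATCH)

    @property
    def target_span(self) -> tuple[int, int]:
        ts = [s.target for s in self.steps if s.target is not None]
        return (min(ts), max(ts))

    @property
    def query_span(self) -> tuple[int, int]:
        qs = [s.query for s in self.steps if s.query is not None]
        return (min(qs), max(qs))


@dataclass
class AlignedTrack:
    track: Track
    segments: list[AlignmentSegment]
    total_score: float
    row: int = -1

    @property
    def query_extent(self) -> tuple[int, int]:
        lo = min(seg.query_span[0] for seg in self.segments)
        hi = max(seg.query_span[1] for seg in self.segments)
        return (lo, hi)


def _trim_and_score(steps: list[Step], scoring: ScoringScheme) -> Optional[AlignmentSegment]:
    """Trim leading/trailing non-match steps and rescore; None if matchless."""
    first = next((i for i, s in enumerate(steps) if s.state is StepState.MATCH), None)
    if first is None:
        return None
    last = max(i for i, s in enumerate(steps) if s.state is StepState.MATCH)
    trimmed = steps[first : last + 1]
    score = sum(scoring.step_score(s.state) for s in trimmed)
    return AlignmentSegment(Orientation.FORWARD, trimmed, score)


def smith_waterman(
    query: FamilySequence, target: FamilySequence, scoring: ScoringScheme
) -> Optional[AlignmentSegment]:
    """Best single local alignment; None when its score < score_threshold.

    Tie-break: among equal-scoring end cells the smallest (target end, query
    end) is chosen and the traceback prefers diagonal over target-gap over
    query-gap, which yields the segment with the smallest target start among
    the canonical tracebacks.
    """
    n, m = len(target), len(query)
    qf, tf = query.families, target.families
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        ti = tf[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if families_match(ti, qf[j - 1]) else scoring.mismatch
            v = max(0.0, Hp[j - 1] + s, Hp[j] + scoring.gap, Hi[j - 1] + scoring.gap)
            Hi[j] = v
            if v > best:
                best, best_cell = v, (i, j)
    if best_cell is None or best < scoring.score_threshold:
        return None
    steps: list[Step] = []
    i, j = best_cell
    while i > 0 and j > 0 and H[i][j] > 0:
        s = scoring.match if families_match(tf[i - 1], qf[j - 1]) else scoring.mismatch
        state = StepState.MATCH if s == scoring.match else StepState.SUBSTITUTION
        if H[i][j] == H[i - 1][j - 1] + s:
            steps.append(Step(j - 1, i - 1, state))
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + scoring.gap:
            steps.append(Step(None, i - 1, StepState.INSERTION))
            i -= 1
        else:
            steps.append(Step(j - 1, None, StepState.DELETION))
            j -= 1
    steps.reverse()
    return _trim_and_score(steps, scoring)


def repeat_align(
    query: FamilySequence, target: FamilySequence, scoring: ScoringScheme
) -> list[AlignmentSegment]:
    """Repeated-matches DP: non-overlapping (in target) local matches of the
    query against the target, each scoring >= repeat_T.

    The unmatched state threads through the target; opening a segment is
    free, closing one costs repeat_T, so only segments worth at least the
    threshold survive.  On ties the traceback prefers closing a segment, so a
    segment scoring exactly repeat_T is reported rather than dropped.
    """
    n, m = len(target), len(query)
    qf, tf = query.families, target.families
    T, g = scoring.repeat_T, scoring.gap
    # F[i][j]: best score inside a segment, target consumed through i, query
    # cursor at j.  F0[i]: best score in the unmatched state at target i.
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F0 = [0.0] * (n + 1)
    ptr: list[list[Optional[str]]] = [[None] * (m + 1) for _ in range(n + 1)]
    close_at: list[Optional[int]] = [None] * (n + 1)
    for i in range(1, n + 1):
        Fi, Fp = F[i], F[i - 1]
        pi = ptr[i]
        ti = tf[i - 1]
        start_base = F0[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if families_match(ti, qf[j - 1]) else scoring.mismatch
            diag = Fp[j - 1] + s
            start = start_base + s
            up = Fp[j] + g
            left = Fi[j - 1] + g
            v = max(diag, start, up, left)
            Fi[j] = v
            if v == diag:
                pi[j] = "diag"
            elif v == start:
                pi[j] = "start"
            elif v == up:
                pi[j] = "up"
            else:
                pi[j] = "left"
        # unmatched state: skip target gene i, or close the best open segment
        F0[i] = F0[i - 1]
        for j in range(1, m + 1):
            if Fi[j] - T >= F0[i]:  # >= : prefer closing on ties
                if Fi[j] - T > F0[i] or close_at[i] is None:
                    F0[i] = Fi[j] - T
                    close_at[i] = j
    # Traceback along the unmatched chain, peeling off closed segments.
    # close_at[i], when set, always corresponds to the final value of F0[i].
    segments: list[AlignmentSegment] = []
    i = n
    while i > 0:
        j = close_at[i]
        if j is None:
            i -= 1
            continue
        seg_steps: list[Step] = []
        while True:
            p = ptr[i][j]
            s = scoring.match if families_match(tf[i - 1], qf[j - 1]) else scoring.mismatch
            state = StepState.MATCH if s == scoring.match else StepState.SUBSTITUTION
            if p in ("diag", "start"):
                seg_steps.append(Step(j - 1, i - 1, state))
                i, j = i - 1, j - 1
                if p == "start":
                    break
            elif p == "up":
                seg_steps.append(Step(None, i - 1, StepState.INSERTION))
                i -= 1
            else:  # left
                seg_steps.append(Step(j - 1, None, StepState.DELETION))
                j -= 1
        seg_steps.reverse()
        seg = _trim_and_score(seg_steps, scoring)
        if seg is not None and seg.score >= T:
            segments.append(seg)
    segments.reverse()
    return segments


def weighted_interval_schedule(
    intervals: Sequence[tuple[float, float, float]]
) -> tuple[list[int], float]:
    """Exact maximum-total-weight non-overlapping subset of half-open
    intervals (start, end, weight); end > start required.

    Returns (selected original indices ascending, total weight).  Ties in
    total weight are broken toward the lexicographically earliest index set.
    """
    for s, e, _ in intervals:
        if e <= s:
            raise ValueError("interval end must be > start")
    n = len(intervals)
    if n == 0:
        return [], 0.0
    order = sorted(range(n), key=lambda k: (intervals[k][1], intervals[k][0], k))
    ends = [intervals[k][1] for k in order]
    # dp[t] = (weight, chosen original-index tuple) using the first t sorted
    dp: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    for t in range(1, n + 1):
        k = order[t - 1]
        s, e, w = intervals[k]
        p = bisect.bisect_right(ends, s, 0, t - 1)
        take_w, take_set = dp[p][0] + w, tuple(sorted(dp[p][1] + (k,)))
        skip_w, skip_set = dp[t - 1]
        if take_w > skip_w or (take_w == skip_w and take_set < skip_set):
            dp.append((take_w, take_set))
        else:
            dp.append((skip_w, skip_set))
    weight, chosen = dp[n]
    return list(chosen), weight


def _remap_reversed(seg: AlignmentSegment, n_target: int) -> AlignmentSegment:
    """Map a segment computed on the reversed target back to original target
    coordinates; target indices then decrease as query indices increase."""
    steps = [
        Step(s.query, None if s.target is None else n_target - 1 - s.target, s.state)
        for s in seg.steps
    ]
    return AlignmentSegment(Orientation.INVERTED, steps, seg.score)


def _split_forward(
    seg: AlignmentSegment, forbidden: set[int], scoring: ScoringScheme
) -> list[AlignmentSegment]:
    """Pieces of a forward segment with target positions in ``forbidden``
    removed; each piece is re-trimmed to match endpoints and kept when it
    still clears repeat_T on its own."""
    pieces: list[AlignmentSegment] = []
    run: list[Step] = []
    for step in seg.steps:
        if step.target is not None and step.target in forbidden:
            if run:
                piece = _trim_and_score(run, scoring)
                if piece is not None and piece.score >= scoring.repeat_T:
                    pieces.append(piece)
                run = []
        else:
            run.append(step)
    if run:
        piece = _trim_and_score(run, scoring)
        if piece is not None and piece.score >= scoring.repeat_T:
            pieces.append(piece)
    return pieces


def detect_inversions(
    query: FamilySequence,
    target: FamilySequence,
    scoring: ScoringScheme,
    forward_segments: Sequence[AlignmentSegment],
) -> list[AlignmentSegment]:
    """Add inverted segments to a forward alignment.

    Candidate inverted segments come from the repeated-matches DP run against
    the reversed target.  Forward segments, their pieces cut at candidate
    spans (so an inversion inside a long conserved run can displace exactly
    the stretch it explains), and the candidates themselves compete as
    weighted intervals on the target axis; the exact maximum-weight
    non-overlapping subset is returned, ordered by target start.  The
    selected weight never falls below that of the forward segments alone.
    """
    n = len(target)
    inverted = [
        _remap_reversed(c, n)
        for c in repeat_align(query, target.reversed(), scoring)
    ]
    inverted = [c for c in inverted if c.n_matches >= MIN_INVERTED_MATCHES]
    if not inverted:
        return sorted(forward_segments, key=lambda s: s.target_span)
    forbidden: set[int] = set()
    for c in inverted:
        lo, hi = c.target_span
        forbidden.update(range(lo, hi + 1))
    candidates: list[AlignmentSegment] = list(forward_segments)
    for seg in forward_segments:
        candidates.extend(_split_forward(seg, forbidden, scoring))
    candidates.extend(inverted)
    intervals = [
        (float(c.target_span[0]), float(c.target_span[1] + 1), c.score)
        for c in candidates
    ]
    chosen, _ = weighted_interval_schedule(intervals)
    return sorted((candidates[k] for k in chosen), key=lambda s: s.target_span)


def greedy_interval_rows(extents: Sequence[tuple[float, float]]) -> list[int]:
    """Greedy first-fit row packing of closed intervals in start order.

    Sweeping intervals by ascending start and placing each in the lowest
    row whose last interval has already ended is the canonical greedy
    coloring of an interval graph: same-row extents never overlap and the
    number of rows equals the maximum point-overlap depth (optimal).  Row
    indices are dense from 0.
    """
    order = sorted(range(len(extents)), key=lambda k: (extents[k][0], extents[k][1], k))
    rows: list[int] = [0] * len(extents)
    row_last_end: list[float] = []
    for k in order:
        lo, hi = extents[k]
        for r, last in enumerate(row_last_end):
            if lo > last:
                rows[k] = r
                row_last_end[r] = hi
                break
        else:
            rows[k] = len(row_last_end)
            row_last_end.append(hi)
    return rows


def layout_rows(aligned: list[AlignedTrack]) -> list[AlignedTrack]:
    """Assign non-overlapping display rows by query-axis extent, in place."""
    if not aligned:
        return aligned
    rows = greedy_interval_rows([t.query_extent for t in aligned])
    for t, r in zip(aligned, rows):
        t.row = r
    return aligned


def align_all(
    query_or_consensus: FamilySequence,
    hits: Sequence,
    scoring: ScoringScheme,
) -> list[AlignedTrack]:
    """Align every search hit to the query (or consensus) family sequence.

    Per hit: repeated-matches alignment, then inversion detection; hits with
    no surviving segment are dropped.  Output is ordered by (score desc,
    source, chromosome, start) with display rows assigned.
    """
    out: list[AlignedTrack] = []
    for hit in hits:
        track = hit.track if hasattr(hit, "track") else hit
        target = track.family_sequence()
        forward = repeat_align(query_or_consensus, target, scoring)
        segments = detect_inversions(query_or_consensus, target, scoring, forward)
        if not segments:
            continue
        out.append(
            AlignedTrack(
                track=track,
                segments=segments,
                total_score=sum(s.score for s in segments),
            )
        )
    out.sort(
        key=lambda t: (-t.total_score, t.track.source, t.track.chromosome, t.track.first)
    )
    return layout_rows(out)
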