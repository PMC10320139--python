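"""Independent brute-force oracles used to validate the dynamic programs.

These deliberately avoid the implementation's algorithmic shortcuts: local
alignment is scored by enumerating global alignments of every substring
pair, the repeated-matches total by chaining those substring scores over all
target split points, interval scheduling by scanning every subset, and
island search by checking every candidate interval for validity and
maximality.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

Fams = Sequence[Optional[str]]


def _fam_eq(a: Optional[str], b: Optional[str]) -> bool:
    return a is not None and a == b


def _start_anchored_scores(
    tf: Fams, qf: Fams, a: int, b: int, match: float, mismatch: float, gap: float
) -> list[list[float]]:
    """Global-alignment scores of t[a:a+i] vs q[b:b+j] for all i, j."""
    n, m = len(tf) - a, len(qf) - b
    dp = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = dp[i - 1][0] + gap
    for j in range(1, m + 1):
        dp[0][j] = dp[0][j - 1] + gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if _fam_eq(tf[a + i - 1], qf[b + j - 1]) else mismatch
            dp[i][j] = max(dp[i - 1][j - 1] + s, dp[i - 1][j] + gap, dp[i][j - 1] + gap)
    return dp


def local_best_score(
    qf: Fams, tf: Fams, match: float, mismatch: float, gap: float
) -> float:
    """Best local alignment score: max global score over all substring pairs
    (the empty alignment scores 0)."""
    best = 0.0
    for a in range(len(tf) + 1):
        for b in range(len(qf) + 1):
            dp = _start_anchored_scores(tf, qf, a, b, match, mismatch, gap)
            best = max(best, max(max(row) for row in dp))
    return best


def repeat_best_net_score(
    qf: Fams, tf: Fams, match: float, mismatch: float, gap: float, T: float
) -> float:
    """Optimal total of disjoint target-segment matches, each charged T.

    seg(a, i) is the best global score of target substring t[a:i] against any
    query substring; the chain DP over target split points maximizes
    sum(seg - T), never forced to take a segment.
    """
    n = len(tf)
    seg = [[float("-inf")] * (n + 1) for _ in range(n + 1)]
    for a in range(n):
        for b in range(len(qf) + 1):
            dp = _start_anchored_scores(tf, qf, a, b, match, mismatch, gap)
            for i in range(1, n - a + 1):
                best_j = max(dp[i])
                if best_j > seg[a][a + i]:
                    seg[a][a + i] = best_j
    best = [0.0] * (n + 1)
    for i in range(1, n + 1):
        best[i] = best[i - 1]
        for a in range(i):
            cand = best[a] + seg[a][i] - T
            if cand > best[i]:
                best[i] = cand
    return best[n]


def wis_brute_force(
    intervals: Sequence[tuple[float, float, float]]
) -> tuple[list[int], float]:
    """Max-weight non-overlapping subset by scanning all subsets; among
    optima, the lexicographically earliest index set."""
    n = len(intervals)
    best_w, best_set = 0.0, ()
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            ok = True
            for x, y in combinations(combo, 2):
                if intervals[x][0] < intervals[y][1] and intervals[y][0] < intervals[x][1]:
                    ok = False
                    break
            if not ok:
                continue
            w = sum(intervals[k][2] for k in combo)
            if w > best_w or (w == best_w and combo < best_set):
                best_w, best_set = w, combo
    return list(best_set), best_w


def islands_brute_force(
    families: Fams, famset: set, matched: int, intermediate: int
) -> list[tuple[int, int, int]]:
    """Maximal valid islands by exhaustive interval enumeration.

    An interval is a valid island when it starts and ends on matching genes
    and no internal run of non-matching genes exceeds ``intermediate``; the
    returned islands are the maximal ones with at least ``matched`` matches.
    """
    mpos = [i for i, f in enumerate(families) if f is not None and f in famset]
    valid = []
    for ai in range(len(mpos)):
        for bi in range(ai, len(mpos)):
            gaps = [mpos[k + 1] - mpos[k] - 1 for k in range(ai, bi)]
            if all(g <= intermediate for g in gaps):
                valid.append((mpos[ai], mpos[bi], bi - ai + 1))
    maximal = [
        v
        for v in valid
        if not any(w != v and w[0] <= v[0] and v[1] <= w[1] for w in valid)
    ]
    return sorted(v for v in maximal if v[2] >= matched)


def levenshtein_recursive(a: Fams, b: Fams) -> int:
    """Edit distance straight from the recursive definition (memoized)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        sub = d(i - 1, j - 1) + (0 if _fam_eq(a[i - 1], b[j - 1]) else 1)
        return min(sub, d(i - 1, j) + 1, d(i, j - 1) + 1)

    return d(len(a), len(b))
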