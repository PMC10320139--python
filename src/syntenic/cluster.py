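"""Query-track clustering and profile-HMM consensus.

Multiple query tracks are clustered by hierarchical agglomerative clustering
on normalized Levenshtein distance over their family sequences.  Each cluster
is then multiple-aligned with a match/insert/delete profile HMM over the
gene-family alphabet, seeded from the cluster medoid, and collapsed to a
consensus family sequence that downstream search and alignment use as the
reference.

Orphan genes are distinct anonymous symbols throughout: an orphan matches
nothing, including another orphan, both in edit distance and in HMM emission
(it always takes the unseen-symbol probability mass).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .model import FamilySequence, SyntenicError, Track, families_match

ORPHAN = "__orphan__"  # consensus-counting category for unannotated genes


def levenshtein(a: FamilySequence, b: FamilySequence) -> int:
    """Unit-cost edit distance over family symbols (orphans match nothing)."""
    af, bf = a.families, b.families
    n, m = len(af), len(bf)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = af[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if families_match(ai, bf[j - 1]) else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[m]


def levenshtein_normalized(a: FamilySequence, b: FamilySequence) -> float:
    """Edit distance divided by the longer length; 0 for two empty sequences."""
    denom = max(len(a), len(b))
    if denom == 0:
        return 0.0
    return levenshtein(a, b) / denom


@dataclass
class ClusterParams:
    linkage: str = "average"
    distance_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "single", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not 0.0 <= self.distance_threshold <= 1.0:
            raise ValueError("distance_threshold must be in [0, 1]")


def cluster_tracks(tracks: Sequence[Track], params: ClusterParams) -> list[list[int]]:
    """Agglomerative clustering of tracks, cut at the distance threshold.

    Returns clusters as lists of track indices, ordered by smallest member.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    if len(tracks) == 1:
        return [[0]]
    seqs = [t.family_sequence() for t in tracks]
    n = len(seqs)
    condensed = [
        levenshtein_normalized(seqs[i], seqs[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    Z = scipy_linkage(condensed, method=params.linkage)
    labels = fcluster(Z, t=params.distance_threshold, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    return sorted(groups.values(), key=min)


# ---------------------------------------------------------------------------
# Profile HMM


_SOURCES = ("M", "I", "D")
_TARGETS = ("M", "I", "D")


def _valid_keys(k: int, ncols: int) -> list[str]:
    """Transition keys available out of column k's states (0 = begin)."""
    keys = []
    for s in _SOURCES:
        if s == "D" and k == 0:
            continue  # no delete state at the begin column
        for t in _TARGETS:
            if t == "D" and k == ncols:
                continue  # no delete state beyond the last column
            keys.append(s + t)
    return keys


@dataclass
class FamilyProfileHMM:
    """Match/insert/delete profile HMM over a gene-family alphabet.

    ``emissions[k]`` holds the counted families of match column k+1;
    any other symbol (including every orphan) emits with ``floor[k]``, the
    pseudocount mass reserved for one unseen category, so each column's
    distribution sums to 1 over alphabet + unseen.
    """

    ncols: int
    alphabet: frozenset
    emissions: list[dict]
    floor: list[float]
    transitions: list[dict]
    insert_emission: float

    def emission_logp(self, col: int, family: Optional[str]) -> float:
        if family is None:
            p = self.floor[col - 1]
        else:
            p = self.emissions[col - 1].get(family, self.floor[col - 1])
        return math.log(p)

    def transition_logp(self, k: int, key: str) -> float:
        p = self.transitions[k].get(key, 0.0)
        return math.log(p) if p > 0 else float("-inf")


_SEED_TRANSITIONS = {
    "MM": 0.90, "MI": 0.05, "MD": 0.05,
    "IM": 0.80, "II": 0.15, "ID": 0.05,
    "DM": 0.80, "DD": 0.15, "DI": 0.05,
}


def _normalized_transitions(counts: dict, k: int, ncols: int, pc: float) -> dict:
    out: dict = {}
    valid = _valid_keys(k, ncols)
    for s in _SOURCES:
        keys = [key for key in valid if key[0] == s]
        if not keys:
            continue
        total = sum(counts.get(key, 0.0) + pc for key in keys)
        for key in keys:
            out[key] = (counts.get(key, 0.0) + pc) / total
    return out


def _emission_table(
    counts_per_col: list[Counter], alphabet: frozenset, pc: float
) -> tuple[list[dict], list[float]]:
    emissions, floor = [], []
    nslots = len(alphabet) + 1  # +1 unseen/orphan category
    for counts in counts_per_col:
        total = sum(counts.values())
        denom = total + pc * nslots
        emissions.append({fam: (c + pc) / denom for fam, c in sorted(counts.items())})
        floor.append(pc / denom)
    return emissions, floor


def _seed_hmm(
    medoid: FamilySequence, alphabet: frozenset, pc: float
) -> FamilyProfileHMM:
    ncols = len(medoid)
    counts = [
        Counter({fam: 1}) if fam is not None else Counter()
        for fam in medoid.families
    ]
    emissions, floor = _emission_table(counts, alphabet, pc)
    transitions = [
        _normalized_transitions(
            {key: _SEED_TRANSITIONS[key] for key in _valid_keys(k, ncols)}, k, ncols, 0.0
        )
        for k in range(ncols + 1)
    ]
    return FamilyProfileHMM(
        ncols=ncols,
        alphabet=alphabet,
        emissions=emissions,
        floor=floor,
        transitions=transitions,
        insert_emission=1.0 / (len(alphabet) + 1),
    )


def viterbi_align(
    hmm: FamilyProfileHMM, seq: FamilySequence
) -> tuple[list[tuple[str, int]], float, list[tuple[str, int]]]:
    """Max-probability path of a family sequence through the profile.

    Returns (per-gene assignments, log-probability, full state path).  The
    assignment for gene i is ("M", column) or ("I", column-inserted-after);
    assigned match columns strictly increase along the sequence.  The full
    state path includes delete states and is what transition re-estimation
    counts.
    """
    L, n = hmm.ncols, len(seq)
    NEG = float("-inf")
    fams = seq.families
    log_ins = math.log(hmm.insert_emission)
    VM = [[NEG] * (n + 1) for _ in range(L + 1)]
    VI = [[NEG] * (n + 1) for _ in range(L + 1)]
    VD = [[NEG] * (n + 1) for _ in range(L + 1)]
    back: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    VM[0][0] = 0.0
    t = hmm.transition_logp
    for k in range(0, L + 1):
        for i in range(0, n + 1):
            if k > 0 and i > 0:
                e = hmm.emission_logp(k, fams[i - 1])
                cands = [
                    (VM[k - 1][i - 1] + t(k - 1, "MM"), ("M", k - 1, i - 1)),
                    (VI[k - 1][i - 1] + t(k - 1, "IM"), ("I", k - 1, i - 1)),
                    (VD[k - 1][i - 1] + t(k - 1, "DM"), ("D", k - 1, i - 1)),
                ]
                best, prev = max(cands, key=lambda c: c[0])
                if best > NEG:
                    VM[k][i] = best + e
                    back[("M", k, i)] = prev
            if k > 0:
                cands = [
                    (VM[k - 1][i] + t(k - 1, "MD"), ("M", k - 1, i)),
                    (VI[k - 1][i] + t(k - 1, "ID"), ("I", k - 1, i)),
                    (VD[k - 1][i] + t(k - 1, "DD"), ("D", k - 1, i)),
                ]
                best, prev = max(cands, key=lambda c: c[0])
                if best > NEG:
                    VD[k][i] = best
                    back[("D", k, i)] = prev
            if i > 0:
                cands = [
                    (VM[k][i - 1] + t(k, "MI"), ("M", k, i - 1)),
                    (VI[k][i - 1] + t(k, "II"), ("I", k, i - 1)),
                    (VD[k][i - 1] + t(k, "DI"), ("D", k, i - 1)),
                ]
                best, prev = max(cands, key=lambda c: c[0])
                if best > NEG:
                    VI[k][i] = best + log_ins
                    back[("I", k, i)] = prev
    ends = [
        (VM[L][n] + t(L, "MM"), ("M", L, n)),
        (VI[L][n] + t(L, "IM"), ("I", L, n)),
        (VD[L][n] + t(L, "DM"), ("D", L, n)),
    ]
    logp, state = max(ends, key=lambda c: c[0])
    if logp == NEG:
        raise SyntenicError("no path through profile HMM")
    path: list[tuple[str, int, int]] = []
    while state != ("M", 0, 0):
        path.append(state)
        state = back[state]
    path.reverse()
    assignments: list[tuple[str, int]] = []
    states: list[tuple[str, int]] = []
    for s, k, i in path:
        states.append((s, k))
        if s == "M":
            assignments.append(("M", k))
        elif s == "I":
            assignments.append(("I", k))
    return assignments, logp, states


def _medoid_index(seqs: Sequence[FamilySequence]) -> int:
    sums = [sum(levenshtein(s, o) for o in seqs) for s in seqs]
    return min(range(len(seqs)), key=lambda i: (sums[i], i))


def build_profile_hmm(
    cluster_seqs: Sequence[FamilySequence], pseudocount: float = 0.1
) -> FamilyProfileHMM:
    """Medoid-seeded profile HMM with one re-estimation pass.

    The architecture has one match column per medoid position.  Members are
    Viterbi-aligned to the seed, then emissions and transitions are
    re-estimated once from the resulting alignment with pseudocounts.  This
    deterministic procedure replaces full Baum-Welch, which near-identical
    query tracks do not need.
    """
    if not cluster_seqs:
        raise SyntenicError("cannot build a profile from an empty cluster")
    alphabet = frozenset(
        f for s in cluster_seqs for f in s.families if f is not None
    )
    medoid = cluster_seqs[_medoid_index(cluster_seqs)]
    if len(medoid) == 0:
        raise SyntenicError("cannot build a profile from empty sequences")
    seed = _seed_hmm(medoid, alphabet, pseudocount)
    ncols = seed.ncols
    em_counts = [Counter() for _ in range(ncols)]
    tr_counts: list[dict] = [{} for _ in range(ncols + 1)]
    for seq in cluster_seqs:
        assignments, _, states = viterbi_align(seed, seq)
        gi = 0
        for s, k in states:
            if s in ("M", "I"):
                if s == "M" and seq.families[gi] is not None:
                    em_counts[k - 1][seq.families[gi]] += 1
                gi += 1
        full = [("M", 0)] + states + [("M", ncols + 1)]
        for (s1, k1), (s2, _k2) in zip(full, full[1:]):
            key = s1 + s2
            tr_counts[k1][key] = tr_counts[k1].get(key, 0) + 1
    emissions, floor = _emission_table(em_counts, alphabet, pseudocount)
    transitions = [
        _normalized_transitions(tr_counts[k], k, ncols, pseudocount)
        for k in range(ncols + 1)
    ]
    return FamilyProfileHMM(
        ncols=ncols,
        alphabet=alphabet,
        emissions=emissions,
        floor=floor,
        transitions=transitions,
        insert_emission=1.0 / (len(alphabet) + 1),
    )


@dataclass
class MSA:
    """A cluster's multiple alignment against its profile HMM."""

    members: list[FamilySequence]
    assignments: list[list[tuple[str, int]]]  # per member, per gene: (state, col)
    medoid_index: int
    hmm: FamilyProfileHMM

    def __post_init__(self) -> None:
        for asn in self.assignments:
            cols = [k for s, k in asn if s == "M"]
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise SyntenicError("match columns must strictly increase")


def build_msa(
    cluster_seqs: Sequence[FamilySequence], pseudocount: float = 0.1
) -> MSA:
    hmm = build_profile_hmm(cluster_seqs, pseudocount)
    assignments = [viterbi_align(hmm, s)[0] for s in cluster_seqs]
    return MSA(
        members=list(cluster_seqs),
        assignments=assignments,
        medoid_index=_medoid_index(cluster_seqs),
        hmm=hmm,
    )


def consensus(msa: MSA) -> FamilySequence:
    """Modal family per match column; ties (and all-delete columns) resolve
    to the medoid's symbol there.  Columns whose mode is orphan stay orphan."""
    if not msa.members:
        raise SyntenicError("empty cluster has no consensus")
    ncols = msa.hmm.ncols
    # medoid family per column, from the medoid's own assignment
    medoid_cols: dict[int, Optional[str]] = {}
    mseq = msa.members[msa.medoid_index]
    for gi, (s, k) in enumerate(msa.assignments[msa.medoid_index]):
        if s == "M":
            medoid_cols[k] = mseq.families[gi]
    col_counts: list[Counter] = [Counter() for _ in range(ncols)]
    for seq, asn in zip(msa.members, msa.assignments):
        for gi, (s, k) in enumerate(asn):
            if s == "M":
                fam = seq.families[gi]
                col_counts[k - 1][fam if fam is not None else ORPHAN] += 1
    out: list[Optional[str]] = []
    for k in range(1, ncols + 1):
        counts = col_counts[k - 1]
        if not counts:
            out.append(medoid_cols.get(k))
            continue
        top = max(counts.values())
        modal = sorted(fam for fam, c in counts.items() if c == top)
        if len(modal) > 1:
            pick = medoid_cols.get(k)
            if pick not in [None if f == ORPHAN else f for f in modal]:
                pick = None if modal[0] == ORPHAN else modal[0]
        else:
            pick = None if modal[0] == ORPHAN else modal[0]
        out.append(pick)
    return FamilySequence.from_families(out)
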