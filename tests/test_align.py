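"""Local alignment, repeated matches, inversion detection, and row layout."""

from __future__ import annotations

import random

import pytest

from helpers import seq_str
from oracles import local_best_score, repeat_best_net_score, wis_brute_force
from syntenic import (
    Orientation,
    ScoringScheme,
    SimParams,
    StepState,
    derive_genome,
    detect_inversions,
    make_ancestor,
    repeat_align,
    smith_waterman,
    weighted_interval_schedule,
)
from syntenic.align import AlignedTrack, greedy_interval_rows, layout_rows
from syntenic.search import SearchHit
from syntenic import align_all
from syntenic.tracks import make_query_track


SC0 = ScoringScheme(score_threshold=0.0)


def random_seq(rng, max_len=8, alphabet="ABC", orphan=False):
    chars = alphabet + ("." if orphan else "")
    return seq_str("".join(rng.choice(chars) for _ in range(rng.randint(0, max_len))))


# -- Smith-Waterman ---------------------------------------------------------

def test_identical_sequences_score_perfectly():
    s = seq_str("ABCDE")
    seg = smith_waterman(s, s, ScoringScheme(match=5.0, score_threshold=0.0))
    assert seg.score == 25.0
    assert [st.state for st in seg.steps] == [StepState.MATCH] * 5


def test_disjoint_alphabets_align_to_nothing():
    assert smith_waterman(seq_str("AAA"), seq_str("BBB"), SC0) is None


def test_threshold_suppresses_weak_alignments():
    seg = smith_waterman(seq_str("AxxB"), seq_str("AyyB"), ScoringScheme(score_threshold=30.0))
    assert seg is None


def test_smith_waterman_matches_brute_force():
    rng = random.Random(17)
    for _ in range(120):
        q, t = random_seq(rng, orphan=True), random_seq(rng, orphan=True)
        seg = smith_waterman(q, t, SC0)
        expect = local_best_score(q.families, t.families, 10.0, -1.0, -1.0)
        got = seg.score if seg is not None else 0.0
        assert got == expect


def test_score_invariant_under_joint_reversal():
    rng = random.Random(23)
    for _ in range(60):
        q, t = random_seq(rng), random_seq(rng)
        a = smith_waterman(q, t, SC0)
        b = smith_waterman(q.reversed(), t.reversed(), SC0)
        assert (a.score if a else 0.0) == (b.score if b else 0.0)


# -- Repeated matches -------------------------------------------------------

def test_duplicated_target_yields_two_segments():
    q = seq_str("ABCDE")
    t = seq_str("ABCDEABCDE")
    segs = repeat_align(q, t, ScoringScheme(repeat_T=10.0))
    assert len(segs) == 2
    assert [s.target_span for s in segs] == [(0, 4), (5, 9)]
    assert all(s.query_span == (0, 4) for s in segs)


def test_unreachable_threshold_yields_no_segments():
    q = seq_str("AB")
    assert repeat_align(q, q, ScoringScheme(repeat_T=1000.0)) == []


def test_single_occurrence_reduces_to_smith_waterman():
    q = seq_str("ABCDE")
    t = seq_str("xxABCDExx")
    segs = repeat_align(q, t, ScoringScheme())
    sw = smith_waterman(q, t, SC0)
    assert len(segs) == 1
    assert segs[0].score == sw.score
    assert segs[0].target_span == sw.target_span


def test_repeat_total_matches_brute_force():
    rng = random.Random(31)
    for T in (5.0, 15.0):
        sc = ScoringScheme(repeat_T=T)
        for _ in range(60):
            q, t = random_seq(rng), random_seq(rng)
            segs = repeat_align(q, t, sc)
            net = sum(s.score for s in segs) - T * len(segs)
            expect = repeat_best_net_score(q.families, t.families, 10.0, -1.0, -1.0, T)
            assert net == expect
            # segments disjoint in target space, each above threshold
            covered: set[int] = set()
            for s in segs:
                lo, hi = s.target_span
                assert s.score >= T
                assert covered.isdisjoint(range(lo, hi + 1))
                covered.update(range(lo, hi + 1))


def test_repeat_total_dominates_single_best_local():
    rng = random.Random(37)
    sc = ScoringScheme(repeat_T=10.0)
    for _ in range(60):
        q, t = random_seq(rng), random_seq(rng)
        sw = smith_waterman(q, t, SC0)
        if sw is None or sw.score < sc.repeat_T:
            continue
        segs = repeat_align(q, t, sc)
        assert sum(s.score for s in segs) >= sw.score


# -- Weighted interval scheduling ------------------------------------------

def test_wis_trivial_cases():
    assert weighted_interval_schedule([]) == ([], 0.0)
    assert weighted_interval_schedule([(0, 5, 3.0)]) == ([0], 3.0)


def test_wis_prefers_optimal_pair_over_greedy_middle():
    chosen, weight = weighted_interval_schedule([(1, 3, 2.0), (2, 5, 4.0), (4, 6, 3.0)])
    assert chosen == [0, 2]
    assert weight == 5.0


def test_wis_matches_subset_search():
    rng = random.Random(41)
    for _ in range(100):
        intervals = []
        for _ in range(rng.randint(0, 10)):
            s = rng.randint(0, 20)
            intervals.append((float(s), float(s + rng.randint(1, 6)), float(rng.randint(1, 9))))
        got = weighted_interval_schedule(intervals)
        assert got == wis_brute_force(intervals)


# -- Inversions -------------------------------------------------------------

def test_forward_only_homology_is_returned_unchanged():
    q = seq_str("ABCDEFGH")
    sc = ScoringScheme()
    fwd = repeat_align(q, q, sc)
    assert detect_inversions(q, q, sc, fwd) == fwd


def test_middle_third_reversal_detected_as_three_segments():
    q = seq_str("ABCDEFGHI")
    t = seq_str("ABCFEDGHI")  # DEF reversed in place
    sc = ScoringScheme(repeat_T=10.0)
    segs = detect_inversions(q, t, sc, repeat_align(q, t, sc))
    kinds = [s.orientation for s in segs]
    assert kinds == [Orientation.FORWARD, Orientation.INVERTED, Orientation.FORWARD]
    assert segs[1].target_span == (3, 5)


def test_single_gene_flip_is_not_an_inversion():
    q = seq_str("ABCDE")
    t = seq_str("ABCDE")
    sc = ScoringScheme()
    segs = detect_inversions(q, t, sc, repeat_align(q, t, sc))
    assert all(s.orientation is Orientation.FORWARD for s in segs)


def test_inversion_never_decreases_selected_weight():
    rng = random.Random(47)
    sc = ScoringScheme(repeat_T=10.0)
    for _ in range(40):
        q, t = random_seq(rng, max_len=12), random_seq(rng, max_len=12)
        fwd = repeat_align(q, t, sc)
        segs = detect_inversions(q, t, sc, fwd)
        assert sum(s.score for s in segs) >= sum(s.score for s in fwd)


def test_simulated_inversion_recovered_exactly():
    params = SimParams(
        n_chromosomes=1, genes_per_chromosome=80, orphan_rate=0.0,
        n_inversions=1, n_deletions=0, n_tandem_dups=0, n_translocations=0,
        min_event_genes=5, max_event_genes=5, seed=13,
    )
    ancestor = make_ancestor(params)
    derived, log = derive_genome(ancestor, params, "d")
    ev = log.events[0]
    q = ancestor.chromosomes["chr1"].family_sequence()
    t = derived.chromosomes["chr1"].family_sequence()
    sc = ScoringScheme()
    segs = detect_inversions(q, t, sc, repeat_align(q, t, sc))
    inverted = [s for s in segs if s.orientation is Orientation.INVERTED]
    assert len(inverted) == 1
    assert inverted[0].target_span == (ev["start"], ev["start"] + ev["length"] - 1)


# -- Layout -----------------------------------------------------------------

def test_disjoint_extents_share_row_identical_extents_stack():
    assert greedy_interval_rows([(0, 4), (6, 9)]) == [0, 0]
    assert greedy_interval_rows([(0, 4), (0, 4)]) == [0, 1]


def test_layout_is_proper_interval_coloring_within_depth():
    rng = random.Random(53)
    for _ in range(50):
        extents = []
        for _ in range(20):
            lo = rng.randint(0, 40)
            extents.append((lo, lo + rng.randint(0, 10)))
        rows = greedy_interval_rows(extents)
        for i in range(len(extents)):
            for j in range(i + 1, len(extents)):
                if rows[i] == rows[j]:
                    a, b = extents[i], extents[j]
                    assert a[1] < b[0] or b[1] < a[0]
        depth = max(
            sum(1 for lo, hi in extents if lo <= x <= hi)
            for x in range(0, 55)
        )
        assert max(rows) + 1 <= depth
        assert sorted(set(rows)) == list(range(max(rows) + 1))


# -- align_all --------------------------------------------------------------

def test_query_aligned_to_itself_is_all_match_row_zero():
    from helpers import source_from_families

    src = source_from_families("s", {"chr1": "ABCDEFGHIJKLMNOP"})
    track = make_query_track(src, "s_chr1_g8", 5)
    hit = SearchHit(track=track, matched_count=len(track), coverage=1.0)
    aligned = align_all(track.family_sequence(), [hit], ScoringScheme())
    assert len(aligned) == 1
    assert aligned[0].row == 0
    steps = [st for seg in aligned[0].segments for st in seg.steps]
    assert all(st.state is StepState.MATCH for st in steps)


def test_align_all_empty_hits():
    assert align_all(seq_str("ABC"), [], ScoringScheme()) == []


def test_align_all_drops_hits_below_threshold(small_ancestor):
    _, src = small_ancestor
    track = make_query_track(src, src.chromosomes["chr1"].genes[30].name, 10)
    hit = SearchHit(track=track, matched_count=len(track), coverage=1.0)
    unrelated = seq_str("ZYXWV")
    assert align_all(unrelated, [hit], ScoringScheme(repeat_T=100.0)) == []
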