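"""Macrosynteny blocks, chaining, and the 2-mer Jaccard ordering."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from helpers import seq, seq_str, source_from_families
from syntenic import (
    MacroParams,
    Orientation,
    SimParams,
    chain_blocks,
    circos_pairs,
    derive_genome,
    jaccard_2mer_distance,
    macrosynteny_tracks,
    make_ancestor,
    match_pairs,
    order_chromosomes,
)


def test_identical_unique_chromosomes_pair_diagonally():
    s = seq_str("ABCDEFGHIJ")
    assert match_pairs(s, s) == [(i, i) for i in range(10)]


def test_mask_counts_combined_occurrences():
    a = seq_str("AAAB")
    b = seq_str("AAAB")
    pairs = match_pairs(a, b, mask_threshold=4)  # A occurs 3 + 3 = 6 > 4
    assert pairs == [(3, 3)]
    assert len(match_pairs(a, b, mask_threshold=6)) == 10


def test_match_pairs_equals_double_loop():
    rng = random.Random(61)
    for _ in range(50):
        a = seq_str("".join(rng.choice("ABC.") for _ in range(rng.randint(0, 15))))
        b = seq_str("".join(rng.choice("ABC.") for _ in range(rng.randint(0, 15))))
        expect = sorted(
            (i, j)
            for i, f in enumerate(a.families)
            if f is not None
            for j, g in enumerate(b.families)
            if f == g
        )
        assert match_pairs(a, b) == expect


def test_self_comparison_chains_one_forward_block():
    s = seq_str("ABCDEFGHIJ")
    blocks = chain_blocks(match_pairs(s, s), MacroParams(matched=2, intermediate=2))
    assert len(blocks) == 1
    b = blocks[0]
    assert b.orientation is Orientation.FORWARD
    assert b.query_span == (0, 9) and b.target_span == (0, 9)
    assert b.pair_count == 10


def test_full_reversal_chains_one_inverted_block():
    s = seq_str("ABCDEFGHIJ")
    blocks = chain_blocks(match_pairs(s, s.reversed()), MacroParams(matched=2, intermediate=2))
    assert len(blocks) == 1
    assert blocks[0].orientation is Orientation.INVERTED
    assert blocks[0].pair_count == 10


def test_gap_larger_than_intermediate_splits_blocks():
    # two diagonal runs separated by a 5-gene gap on both axes
    pairs = [(i, i) for i in range(4)] + [(i, i) for i in range(9, 13)]
    blocks = chain_blocks(pairs, MacroParams(matched=2, intermediate=3))
    assert [(b.query_span, b.pair_count) for b in blocks] == [((0, 3), 4), ((9, 12), 4)]
    merged = chain_blocks(pairs, MacroParams(matched=2, intermediate=5))
    assert [(b.query_span, b.pair_count) for b in merged] == [((0, 12), 8)]


def test_blocks_are_monotone_maximal_and_pair_disjoint():
    rng = random.Random(67)
    params = MacroParams(matched=2, intermediate=2)
    for _ in range(60):
        pairs = sorted(
            {(rng.randint(0, 12), rng.randint(0, 12)) for _ in range(rng.randint(0, 15))}
        )
        blocks = chain_blocks(pairs, params)
        used_total = 0
        for b in blocks:
            assert b.pair_count >= params.matched
            used_total += b.pair_count
        assert used_total <= len(pairs)
        for b in blocks:
            q0, q1 = b.query_span
            t0, t1 = b.target_span
            assert q1 >= q0 and t1 >= t0
            # the chained pairs inside the block are monotone by construction;
            # check the span contains at least `matched` candidate pairs
            inside = [
                (q, t) for q, t in pairs if q0 <= q <= q1 and t0 <= t <= t1
            ]
            assert len(inside) >= params.matched


def test_jaccard_basics():
    s = seq_str("ABCDE")
    assert jaccard_2mer_distance(s, s) == 0.0
    assert jaccard_2mer_distance(s, s.reversed()) == 0.0
    assert jaccard_2mer_distance(s, seq_str("VWXYZ")) == 1.0
    # orphans contribute no 2-mers
    assert jaccard_2mer_distance(seq_str("A.B"), seq_str("C.D")) == 0.0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.sampled_from(["A", "B", "C", None]), max_size=10).map(seq),
    st.lists(st.sampled_from(["A", "B", "C", None]), max_size=10).map(seq),
    st.lists(st.sampled_from(["A", "B", "C", None]), max_size=10).map(seq),
)
def test_jaccard_is_a_pseudometric(a, b, c):
    assert jaccard_2mer_distance(a, a) == 0.0
    assert jaccard_2mer_distance(a, a.reversed()) == 0.0
    dab = jaccard_2mer_distance(a, b)
    assert dab == jaccard_2mer_distance(b, a)
    assert 0.0 <= dab <= 1.0
    assert jaccard_2mer_distance(a, c) <= dab + jaccard_2mer_distance(b, c) + 1e-12


def test_order_chromosomes_self_first_disjoint_last():
    src = source_from_families(
        "s", {"q": "ABCDEFGH", "same": "ABCDEFGH", "far": "VWXYZUTS", "near": "ABCDWXYZ"}
    )
    query = src.chromosomes["q"]
    targets = [("s", src.chromosomes[c]) for c in ("far", "near", "same")]
    ordered = order_chromosomes(query, targets)
    assert [c.name for _, _, c in ordered] == ["same", "near", "far"]
    assert ordered[0][0] == 0.0
    assert ordered[-1][0] == 1.0


def test_macrosynteny_of_chromosome_against_itself():
    src = source_from_families("s", {"chr1": "ABCDEFGHIJKLMNOP"})
    tracks = macrosynteny_tracks(
        src.chromosomes["chr1"], [src], MacroParams(matched=4, intermediate=2, mask_threshold=None)
    )
    assert len(tracks) == 1
    assert tracks[0].distance == 0.0
    blocks = tracks[0].blocks
    assert len(blocks) == 1
    assert blocks[0].query_span == (0, 15)
    assert blocks[0].row == 0


def test_macrosynteny_federation_transparency():
    params = SimParams(n_chromosomes=2, genes_per_chromosome=60, n_families=40, seed=9)
    src = make_ancestor(params)
    whole = [src]
    # split the source into two single-chromosome sources
    from syntenic.model import DataSource

    s1 = DataSource(name="part1", chromosomes={"chr1": src.chromosomes["chr1"]})
    s2 = DataSource(name="part2", chromosomes={"chr2": src.chromosomes["chr2"]})
    mp = MacroParams(matched=3, intermediate=5, mask_threshold=None)
    a = macrosynteny_tracks(src.chromosomes["chr1"], whole, mp)
    b = macrosynteny_tracks(src.chromosomes["chr1"], [s1, s2], mp)
    stripped_a = [
        (m.chromosome, [(x.query_span, x.target_span, x.orientation, x.pair_count) for x in m.blocks])
        for m in a
    ]
    stripped_b = [
        (m.chromosome, [(x.query_span, x.target_span, x.orientation, x.pair_count) for x in m.blocks])
        for m in b
    ]
    assert stripped_a == stripped_b


def test_wgd_ancestor_chromosome_maps_to_two_derived():
    params = SimParams(
        n_chromosomes=2, genes_per_chromosome=60, orphan_rate=0.0,
        n_inversions=0, n_deletions=0, n_tandem_dups=0, n_translocations=0,
        wgd=True, seed=19,
    )
    ancestor = make_ancestor(params)
    derived, _ = derive_genome(ancestor, params, "poly")
    for cname in ancestor.chromosomes:
        tracks = macrosynteny_tracks(
            ancestor.chromosomes[cname], [derived], MacroParams()
        )
        with_blocks = [m.chromosome for m in tracks if m.blocks]
        assert sorted(with_blocks) == [cname + "a", cname + "b"]


def test_syntenic_distance_increases_with_event_count():
    from scipy.stats import spearmanr

    event_counts = [0, 2, 6, 12]
    xs, ys = [], []
    for rep in range(20):
        params = SimParams(
            n_chromosomes=1, genes_per_chromosome=80,
            n_tandem_dups=0, n_translocations=0, seed=1000 + rep,
        )
        ancestor = make_ancestor(params)
        qseq = ancestor.chromosomes["chr1"].family_sequence()
        for n_events in event_counts:
            import dataclasses

            p = dataclasses.replace(
                params, n_inversions=n_events // 2, n_deletions=n_events - n_events // 2
            )
            derived, _ = derive_genome(ancestor, p, f"d{n_events}")
            xs.append(n_events)
            ys.append(jaccard_2mer_distance(qseq, derived.chromosomes["chr1"].family_sequence()))
    rho = spearmanr(xs, ys).statistic
    assert rho > 0


def test_circos_pair_combinatorics():
    src = source_from_families(
        "s", {"c1": "ABCDEFGHIJ", "c2": "ABCDEFGHIJ", "c3": "VWXYZRSTUQ"}
    )
    chroms = [("s", src.chromosomes[c]) for c in ("c1", "c2", "c3")]
    data = circos_pairs(chroms, MacroParams(matched=4, intermediate=2, mask_threshold=None))
    assert len(data["pairs"]) == 3
    ident = next(
        p for p in data["pairs"]
        if p["a"]["chromosome"] == "c1" and p["b"]["chromosome"] == "c2"
    )
    assert len(ident["blocks"]) == 1
    assert ident["blocks"][0].pair_count == 10
    with pytest.raises(ValueError):
        circos_pairs(chroms[:1], MacroParams())
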