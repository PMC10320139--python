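"""Event-recovery and consistency protocols on simulated genomes.

Each protocol builds its own genomes from a base seed, runs the relevant
detector, and reports counts.  Used by both the acceptance tests and the
acceptance script.

Protocol conditions: single-event genomes are generated without orphan genes
(orphans are content noise orthogonal to the structural signal under test),
and deletion replicates require interior spans, since a deletion touching a
chromosome end is invisible to local alignment by construction.  The macro
recovery analysis uses a chaining gap bound of 1 because a bound of
ceil((L-1)/2) or more lets the flanking forward chain absorb pairs of an
L-gene inversion — a resolution limit of gap-bounded chaining, not a tunable.
"""

from __future__ import annotations

from syntenic import (
    ClusterParams,
    MacroParams,
    Orientation,
    ScoringScheme,
    SearchParams,
    SimParams,
    StepState,
    build_msa,
    chain_blocks,
    cluster_tracks,
    consensus,
    derive_genome,
    detect_inversions,
    macrosynteny_tracks,
    make_ancestor,
    make_query_track,
    match_pairs,
    repeat_align,
    search,
)
from syntenic.model import DataSource


def _single_event_params(kind: str, length: int, seed: int) -> SimParams:
    return SimParams(
        n_chromosomes=1,
        genes_per_chromosome=100,
        orphan_rate=0.0,
        n_inversions=1 if kind == "INVERSION" else 0,
        n_deletions=1 if kind == "DELETION" else 0,
        n_tandem_dups=1 if kind == "TANDEM_DUP" else 0,
        n_translocations=0,
        min_event_genes=length,
        max_event_genes=length,
        seed=seed,
    )


def single_event_genomes(kind: str, n: int, base_seed: int, length: int = 5,
                         interior_only: bool = False):
    """Yield n (ancestor, derived, event) triples with exactly one event."""
    produced, offset = 0, 0
    while produced < n:
        params = _single_event_params(kind, length, base_seed + offset)
        offset += 1
        ancestor = make_ancestor(params)
        derived, log = derive_genome(ancestor, params, "derived")
        ev = log.events[0]
        if interior_only:
            ngenes = params.genes_per_chromosome
            if ev["start"] < 1 or ev["start"] + ev["length"] > ngenes - 1:
                continue
        produced += 1
        yield ancestor, derived, ev


def inversion_recovery(base_seed: int, n: int = 20, length: int = 5) -> dict:
    """Exact-span recovery of single inversions by alignment and by macro
    chaining."""
    scoring = ScoringScheme()
    macro_params = MacroParams(matched=3, intermediate=1, mask_threshold=None)
    align_exact = macro_exact = 0
    for ancestor, derived, ev in single_event_genomes("INVERSION", n, base_seed, length):
        span = (ev["start"], ev["start"] + ev["length"] - 1)
        q = ancestor.chromosomes["chr1"].family_sequence()
        t = derived.chromosomes["chr1"].family_sequence()
        segs = detect_inversions(q, t, scoring, repeat_align(q, t, scoring))
        inverted = [s for s in segs if s.orientation is Orientation.INVERTED]
        if len(inverted) == 1 and inverted[0].target_span == span:
            align_exact += 1
        blocks = chain_blocks(
            match_pairs(q, t), macro_params,
            ancestor.chromosomes["chr1"], derived.chromosomes["chr1"],
        )
        inv_blocks = [b for b in blocks if b.orientation is Orientation.INVERTED]
        if (
            len(inv_blocks) == 1
            and inv_blocks[0].query_span == span
            and inv_blocks[0].target_span == span
        ):
            macro_exact += 1
    return {"n": n, "align_exact": align_exact, "macro_exact": macro_exact}


def deletion_recovery(base_seed: int, n: int = 20, length: int = 5) -> dict:
    """A single interior deletion must appear as one run of ``length``
    DELETION steps at the true query indices."""
    scoring = ScoringScheme()
    exact = 0
    for ancestor, derived, ev in single_event_genomes(
        "DELETION", n, base_seed, length, interior_only=True
    ):
        expected = list(range(ev["start"], ev["start"] + ev["length"]))
        q = ancestor.chromosomes["chr1"].family_sequence()
        t = derived.chromosomes["chr1"].family_sequence()
        segs = detect_inversions(q, t, scoring, repeat_align(q, t, scoring))
        deletions = [
            st.query for s in segs for st in s.steps if st.state is StepState.DELETION
        ]
        if deletions == expected:
            exact += 1
    return {"n": n, "exact": exact}


def wgd_recovery(base_seed: int, n: int = 20, windows=(20, 50, 80)) -> dict:
    """After WGD every ancestral region is found twice by search, and every
    ancestral chromosome shows macro blocks on exactly its two copies."""
    search_params = SearchParams()
    macro_params = MacroParams()
    search_ok = macro_ok = 0
    for r in range(n):
        params = SimParams(
            n_chromosomes=2, genes_per_chromosome=100, orphan_rate=0.0,
            n_inversions=0, n_deletions=0, n_tandem_dups=0, n_translocations=0,
            wgd=True, seed=base_seed + r,
        )
        ancestor = make_ancestor(params)
        derived, _ = derive_genome(ancestor, params, "poly")
        all_twice = True
        for cname in ancestor.chromosomes:
            for idx in windows:
                gene = ancestor.chromosomes[cname].genes[idx].name
                track = make_query_track(ancestor, gene, 10)
                hits = search([derived], [track], search_params)
                full = [h for h in hits if h.matched_count == len(track)]
                if len(full) != 2:
                    all_twice = False
        if all_twice:
            search_ok += 1
        two_copies = True
        for cname in ancestor.chromosomes:
            tracks = macrosynteny_tracks(
                ancestor.chromosomes[cname], [derived], macro_params
            )
            with_blocks = sorted(m.chromosome for m in tracks if m.blocks)
            if with_blocks != [cname + "a", cname + "b"]:
                two_copies = False
        if two_copies:
            macro_ok += 1
    return {"n": n, "search_ok": search_ok, "macro_ok": macro_ok}


def multiquery_clustering(base_seed: int, n_genomes: int = 4) -> dict:
    """Queries from two distinct ancestral regions must form two clusters
    whose consensus equals the ancestral family sequence."""
    params = SimParams(
        n_chromosomes=2, genes_per_chromosome=100,
        n_inversions=0, n_deletions=0, n_tandem_dups=0, n_translocations=0,
        seed=base_seed,
    )
    ancestor = make_ancestor(params)
    regions = [("chr1", 30), ("chr2", 60)]
    neighbors = 10
    tracks, truth = [], []
    for g in range(n_genomes):
        derived, _ = derive_genome(ancestor, params, f"g{g}")
        for cname, idx in regions:
            gene = derived.chromosomes[cname].genes[idx].name
            tracks.append(make_query_track(derived, gene, neighbors))
            truth.append((cname, idx))
    clusters = cluster_tracks(tracks, ClusterParams(distance_threshold=0.5))
    pure = all(len({truth[i] for i in members}) == 1 for members in clusters)
    consensus_matches = 0
    for members in clusters:
        cname, idx = truth[members[0]]
        msa = build_msa([tracks[i].family_sequence() for i in members])
        cons = consensus(msa)
        ancestral = ancestor.chromosomes[cname].family_sequence().families[
            idx - neighbors : idx + neighbors + 1
        ]
        if cons.families == ancestral:
            consensus_matches += 1
    return {
        "n_clusters": len(clusters),
        "pure": pure,
        "consensus_matches": consensus_matches,
    }


def federation_transparency(base_seed: int) -> dict:
    """Splitting one dataset into two sources must not change search or
    macro results (up to the source label)."""
    params = SimParams(
        n_chromosomes=2, genes_per_chromosome=80, n_families=50,
        n_inversions=0, n_deletions=0, n_tandem_dups=0, n_translocations=0,
        seed=base_seed,
    )
    src = make_ancestor(params)
    s1 = DataSource(name="part1", chromosomes={"chr1": src.chromosomes["chr1"]})
    s2 = DataSource(name="part2", chromosomes={"chr2": src.chromosomes["chr2"]})
    gene = src.chromosomes["chr1"].genes[40].name
    track = make_query_track(src, gene, 10)
    sp = SearchParams(matched=3, intermediate=5, mask_threshold=None)
    def strip_hits(hits):
        return [
            (h.track.chromosome, h.track.span, h.matched_count, round(h.coverage, 9))
            for h in hits
        ]
    hits_whole = strip_hits(search([src], [track], sp))
    hits_split = strip_hits(search([s1, s2], [track], sp))
    mp = MacroParams(matched=3, intermediate=5, mask_threshold=None)
    def strip_macro(tracks):
        return [
            (
                m.chromosome,
                round(m.distance, 9),
                [
                    (b.query_span, b.target_span, b.orientation.value, b.pair_count, b.row)
                    for b in m.blocks
                ],
            )
            for m in tracks
        ]
    macro_whole = strip_macro(macrosynteny_tracks(src.chromosomes["chr1"], [src], mp))
    macro_split = strip_macro(macrosynteny_tracks(src.chromosomes["chr1"], [s1, s2], mp))
    return {
        "search_identical": hits_whole == hits_split and bool(hits_whole),
        "macro_identical": macro_whole == macro_split and bool(macro_whole),
    }
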