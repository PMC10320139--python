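# Methods

This note documents the models and algorithms implemented in `syntenic`,
the parameters that matter, the numerical and design choices made where the
design was genuinely open, and the limits of what the simulation-based tests
demonstrate.

## Representation

All computation happens in *gene-rank space* over a *gene-family alphabet*.
A chromosome or track is reduced to its `FamilySequence`: the ordered list
of (family identifier, strand) pairs of its genes. Two genes are equal iff
they carry the same non-orphan family identifier; strand never enters symbol
equality (orientation is recovered at the segment level instead). An orphan
gene — one with no family assignment — is a distinct anonymous symbol that
matches nothing, *including other orphans*. One consequence is that the edit
distance below is a pseudometric: a sequence containing orphans has nonzero
distance to an identical-looking sequence, which is the desired behavior
when the two sequences come from different tracks (two unannotated genes
carry no evidence of homology). Internal coordinates are 0-based half-open;
GFF3 I/O converts to and from the external 1-based inclusive convention.
Gene order is defined by start position, with ties broken by end then name,
so overlapping genes have a reproducible rank.

## Microsynteny search (gaps and islands)

Given query tracks, the query family set is the union of their non-orphan
families, optionally minus families whose genome-wide occurrence count in
the searched source exceeds `mask_threshold` (masking of promiscuous
families; the count is per source, so masking is a property of the data
searched, not of the query). Each chromosome is scanned once: runs of
matching genes in which consecutive matches are separated by at most
`intermediate` non-matching genes form islands, trimmed to matching
endpoints; islands with at least `matched` matching genes become result
tracks. `matched` counts matching *genes* by default so tandem arrays
strengthen a hit; `matched_distinct` switches to counting distinct families.
Orphans always count as non-matching intermediates. Defaults: `matched=4`,
`intermediate=5`, no masking, `neighbors=10`. Self-hits (the query region
re-found) are returned and left to display logic to keep or hide. Searching
sources independently makes federation exact: results over `[S1, S2]` equal
the concatenation of per-source results.

## Track alignment

Scoring is near-binary: a family match is strong evidence (+10 by default)
while substitutions and indels are mild (−1 each), since at family
resolution a mismatch usually means gene content change rather than noisy
signal. `score_threshold` (default 30, i.e. three matched genes) suppresses
spurious single local alignments; `repeat_T` (default 10) is the
per-segment admission threshold of the repeated-matches DP.

*Smith–Waterman* gives the best single local alignment. The
*repeated-matches DP* (an unmatched state threads the target; opening a
segment is free, closing costs `repeat_T`) yields multiple local matches of
the query in the target, pairwise disjoint in target coordinates — this is
what renders tandem and whole-genome duplications as multiple segments. The
segments of one aligned track may legitimately overlap in *query*
coordinates (two homoeologous copies both align to the full query); only
target-coordinate disjointness is enforced. On ties the traceback prefers
closing a segment, so a segment scoring exactly `repeat_T` is reported;
segments are trimmed to begin and end on matches.

*Inversions.* Candidate inverted segments are produced by running the
repeated-matches DP against the reversed target and mapping the result back
(target indices decrease as query indices increase). A candidate needs at
least two matches: a single-gene "inversion" is a strand flip, not
structure. Forward segments, the candidates, and additionally the *pieces*
of each forward segment obtained by cutting it at candidate target spans
(re-trimmed to match endpoints and kept only if they clear `repeat_T` on
their own) all compete as weighted intervals on the target axis; an exact
weighted-interval-scheduling DP (sort + binary search, ties broken toward
the lexicographically earliest candidate-index set) selects the
maximum-weight non-overlapping subset. The piece refinement matters: an
inversion embedded in a long conserved run is otherwise invisible, because
the forward DP bridges it (crossing a 5-gene inversion forward costs ~4
substitutions — the middle gene of an odd-length inversion still matches —
which is cheaper than closing and reopening a segment), and interval
scheduling cannot split an interval it is given. Ordering unsplit forward
segments before pieces and inverted candidates makes ties resolve in favor
of the simpler forward interpretation, so chance 2-gene reverse-adjacencies
do not fragment an alignment they cannot improve.

*Row layout.* Aligned tracks are packed into display rows by a greedy sweep
in ascending query-extent start order, placing each track in the lowest row
whose previous occupant has ended — the canonical greedy coloring of an
interval graph, which uses exactly as many rows as the maximum point-overlap
depth. (First-fit in earliest-finish order was considered and rejected: it
is not depth-optimal.)

## Multi-query clustering and consensus

Tracks are clustered by hierarchical agglomerative clustering (scipy;
average linkage by default, single/complete available) on Levenshtein
distance normalized by the longer sequence length, cut at
`distance_threshold` (default 0.5 — half the track differing). The distance
is computed in-package because the orphan-as-unique-symbol rule and the
unbounded family alphabet rule out byte-oriented libraries; tests
cross-check it against `edlib` on orphan-free instances and against the
recursive definition.

Each cluster's profile HMM has one match column per position of the cluster
*medoid* (minimum summed distance; ties to the first member), match/insert/
delete states, and is trained by a single deterministic pass: members are
Viterbi-aligned to the medoid-seeded profile, then emissions and transitions
are re-estimated once from the alignment with pseudocounts (default 0.1).
Near-identical query tracks do not need Baum–Welch, and the seeded pass is
reproducible. Emissions are distributions over the cluster's family alphabet
plus one reserved "unseen" slot; every orphan symbol emits with the unseen
mass, so orphans never attract a column. Seed transitions favor matches
(M→M 0.9); insert emission is uniform over alphabet + unseen. The consensus
takes each match column's modal family (members' assigned symbols; orphans
pooled as one category), with ties resolved to the medoid's symbol at that
column; all-delete columns fall back to the medoid. Search result tracks
are aligned to the consensus when a cluster has more than one member.

## Macrosynteny

Gene pairs sharing a non-orphan family — with families whose combined
occurrence count on the two chromosomes exceeds `mask_threshold` (default
10) masked, since tandem-heavy families otherwise explode the pair list —
are chained greedily in (query, target) order. A chain absorbs the eligible
next pair with the smallest query index (then smallest target jump):
strictly increasing query index, per-step gaps at most `intermediate` gene
ranks on *both* axes, and target index moving monotonically in the chain's
orientation, which is fixed by its first two members (hence `matched >= 2`
is a type-level requirement; default 10). Chains with at least `matched`
pairs become blocks; a pair belongs to at most one block. Gaps are measured
in gene-index units, not base pairs, because gene-rank space is what family
sequences define. This greedy gap-bounded chaining is a deliberate
simplification of MCScanX's scored DP; at family resolution the blocks are
essentially the same and the procedure is deterministic and parameter-light.

Display order of target chromosomes uses a 2-mer multiset Jaccard distance:
adjacent non-orphan family pairs, canonicalized to unordered form so the
distance is invariant under full-sequence reversal (inversions do not
inflate it); distance = 1 − |multiset ∩| / |multiset ∪|, a pseudometric in
[0, 1]. It is computed on whole-chromosome family sequences. Blocks are
row-packed per chromosome with the same interval coloring as aligned
tracks. The all-pairs (Circos) output chains every unordered chromosome
pair and reports spans in both gene-index and base-pair coordinates.

## Simulator

`make_ancestor` lays out `n_chromosomes × genes_per_chromosome` genes with
exponential gene lengths (mean 3000 bp, floor 200), constant intergenic
spacing (3000 bp), random strands, and orphans at `orphan_rate` (default
0.05). By default (`n_families=None`) every ancestral gene gets its own
family — the fully resolved, mostly-single-copy regime — so that family
multiplicity arises from the *modeled* duplication events (tandem, WGD)
rather than from vocabulary birthday collisions; an integer `n_families`
draws uniformly with replacement instead. `derive_genome` applies WGD
(every chromosome duplicated with `a`/`b` suffixes and fresh gene names),
then inversions (span reversed, strands flipped), deletions, tandem
duplications (span copied in place), and translocations (span moved to
another chromosome), re-laying out coordinates after the fact; per-gene
lengths are preserved, so replaying the recorded event log reproduces the
derived genome exactly, including coordinates. The log also records each
derived gene's ancestral origin, giving tests a homology ground truth.
Default event counts per derived genome: 2 inversions, 2 deletions, 1
tandem duplication, 1 translocation, spans of 3–10 genes.

What the simulator does *not* emulate: nucleotide sequences, annotation
error, gene-family birth/death, variable intergenic structure, or realistic
branch-length models. Tests passing on these genomes show the algorithms
recover the structural events they model — not that the default parameters
are tuned for any particular real clade.

## Recovery protocols and their resolution limits

The event-recovery analyses use single-event genomes (1 chromosome × 100
genes, or 2 × 100 for WGD) with `orphan_rate=0`: orphans are content noise
orthogonal to the structural signal, and an orphan landing on an event
boundary would change the *observable* span (an orphan endpoint can never
be part of an alignment segment) without the detector being wrong.
Two genuine resolution limits are reflected in the protocols rather than
hidden:

- a deletion touching a chromosome end is invisible to local alignment
  (trailing indels are trimmed by construction), so deletion replicates use
  interior spans;
- gap-bounded chaining can only isolate an inversion of L pairs if the gap
  bound is below ceil((L−1)/2) — otherwise the flanking forward chain
  absorbs its outermost pair — so the macro recovery analysis of 5-gene
  inversions runs with `matched=3, intermediate=1`. Alignment-based
  inversion detection has no such limit and runs at the defaults.

## Determinism and numerics

Every tie in every DP is broken deterministically (documented per function:
smallest target end, earliest candidate-index set, first medoid, leftmost
midpoint). Scores are floats but default parameters are integer-valued, so
comparisons are exact; the only tolerance in the package is 1e−12 slack in
the Jaccard triangle-inequality test. Simulation is driven entirely by
seeded numpy generators (per-genome streams derived from the seed and the
genome name), so identical parameters produce byte-identical output files,
and the full pipeline — which contains no randomness — produces
byte-identical JSON for identical configurations.

## Problem sizes

The test suite and the acceptance script run at desk scale on one CPU in
seconds: oracle comparisons use sequences of length ≤ 8 (alignment), 10
intervals (scheduling), chromosomes of ≤ 30 genes (island search); recovery
analyses use 20 replicates per event type at 100 genes per chromosome.
These sizes were chosen because the brute-force oracles are exponential or
quartic and the properties under test are size-independent.
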