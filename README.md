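# syntenic

Offline microsynteny search, gene-order alignment, and on-demand
macrosynteny over gene-family annotated genomes — with a genome-evolution
simulator that provides ground truth for every algorithm.

## The problem

Collections of annotated genomes within a clade differ by whole-genome
duplications (polyploidy), inversions, translocations, tandem duplications
and gene loss. For questions about *functional content in context*, base-pair
alignment is the wrong resolution: what matters is the ordered sequence of
gene-family assignments along each chromosome. `syntenic` treats each genome
as sequences over a gene-family alphabet and provides:

- **Microsynteny search** — given a query track (a focal gene plus *N*
  neighbors on either side, or a chromosome interval), find all chromosome
  segments across any number of independently loaded data sources whose
  family content is similar. Formulated as fixed-radius near-neighbor search
  and solved with a gaps-and-islands scan: islands of matching genes
  separated by at most `intermediate` non-matching genes, reported when they
  contain at least `matched` matching genes.
- **Track alignment** — result tracks are locally aligned to the query (or
  to a cluster consensus) with Smith–Waterman and the repeated-matches
  dynamic program (Durbin et al.), so duplications appear as multiple
  segments. Inverted segments are found by aligning against the reversed
  target; forward and inverted candidate segments then compete as weighted
  intervals on the target axis and an exact weighted-interval-scheduling DP
  selects the maximum-scoring non-overlapping set. Display rows are packed
  by greedy interval scheduling.
- **Multi-query clustering and consensus** — multiple query tracks are
  clustered by hierarchical agglomerative clustering on normalized
  Levenshtein distance over family sequences; each cluster is
  multiple-aligned with a medoid-seeded profile HMM over the family alphabet
  and collapsed to a consensus track used as the search/alignment reference.
- **Macrosynteny** — chromosome-scale collinearity blocks computed on
  demand by greedy monotone chaining of shared-family gene pairs (a
  simplified MCScanX-style procedure), with per-step gap bounds, forward and
  inverted orientation, promiscuous-family masking, query-relative and
  all-pairs (Circos-style) outputs, and display ordering by an
  inversion-aware 2-mer multiset Jaccard distance.
- **Simulation** — a random ancestor genome evolves by recorded WGD,
  inversion, deletion, tandem-duplication and translocation events; the
  event log replays exactly and is the acceptance surface for recovery
  tests.

Data sources are loaded from GFF3 plus a tab-delimited gene→family
assignment file. Because every computation consumes ordered family lists,
sources from different origins compose transparently (federation): results
over a combined collection equal the union of per-source results.

## Worked example

Simulate an ancestor and two derived genomes (the defaults apply two
inversions, two deletions, one tandem duplication and one translocation per
derived genome; 2 chromosomes × 200 genes):

```sh
syntenic simulate --out data --seed 11 --genomes 2
syntenic search \
  --source ancestor data/ancestor.gff3 data/ancestor.families.tsv \
  --source derived1 data/derived1.gff3 data/derived1.families.tsv \
  --source derived2 data/derived2.gff3 data/derived2.families.tsv \
  --gene ancestor_chr1_g0100 --neighbors 10 \
  --matched 4 --intermediate 5 --json hits.json
syntenic align --input hits.json --json aligned.json
```

The search returns four hits (spans are gene indices, coverage is the
fraction of the query family set found):

```
ancestor:chr1 genes 90-110  matched 20  coverage 1.0
derived1:chr1 genes 82-94   matched 12  coverage 0.6
derived1:chr2 genes 5-12    matched 8   coverage 0.4
derived2:chr1 genes 81-101  matched 20  coverage 1.0
```

The first is the query region re-finding itself (a self-hit, kept by
design). In `derived1` the region was split by a translocation: part of it
now sits on chr2, and the two pieces are found independently. Alignment then
makes structure explicit:

```
ancestor:chr1 row 1  score 199.0  segments [(forward, 20)]
derived2:chr1 row 2  score 199.0  segments [(forward, 2), (inverted, 5), (forward, 13)]
derived1:chr1 row 0  score 119.0  segments [(forward, 12)]
derived1:chr2 row 0  score 80.0   segments [(forward, 8)]
```

`derived2` carries a 5-gene inversion inside the region: the aligner reports
it as an inverted segment flanked by forward segments (match counts 2/5/13
sum to the 20 query-set genes). The two `derived1` fragments do not overlap
on the query axis, so the row packer draws them on the same display row.

Macrosynteny for the same chromosomes:

```sh
syntenic macro --source ancestor data/ancestor.gff3 data/ancestor.families.tsv \
  --source derived1 data/derived1.gff3 data/derived1.families.tsv \
  --query-chromosome ancestor:chr1 --matched 10 --intermediate 10 \
  --json blocks.json --bed blocks.bed
syntenic circos --source ancestor data/ancestor.gff3 data/ancestor.families.tsv \
  --chromosomes ancestor:chr1,ancestor:chr2 --json circos.json
```

`syntenic cluster`, `syntenic dotplot` and `syntenic run --config run.yaml`
(the full pipeline, emitting one deterministic JSON document that echoes
every effective parameter) complete the command set.

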