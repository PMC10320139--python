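"""End-to-end pipeline and the versioned JSON result schema.

The pipeline mirrors an interactive session: build query tracks, cluster
them, derive each cluster's consensus, search every data source per cluster,
align the hits to the consensus, and compute macrosynteny for the query
chromosomes.  The complete effective parameter set is echoed into the output
so any result file is reproducible from its own header ("bookmarkable
state"): rerunning the same configuration yields byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .align import AlignedTrack, AlignmentSegment, ScoringScheme, align_all
from .cluster import ClusterParams, MSA, build_msa, cluster_tracks, consensus
from .io import load_source
from .macro import MacroParams, MacroTrack, SyntenyBlock, macrosynteny_tracks
from .model import DataSource, Gene, NotFoundError, Track
from .search import SearchParams, SearchHit, search
from .tracks import make_query_track, make_track_from_interval

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# JSON views of the domain types


def gene_to_dict(g: Gene) -> dict:
    return {
        "name": g.name,
        "start": g.start,
        "end": g.end,
        "strand": g.strand,
        "family": g.family,
    }


def track_to_dict(t: Track) -> dict:
    query_gene = (
        t.genes[t.query_gene_index].name if t.query_gene_index is not None else None
    )
    return {
        "source": t.source,
        "chromosome": t.chromosome,
        "span": [t.first, t.last],
        "query_gene": query_gene,
        "genes": [gene_to_dict(g) for g in t.genes],
    }


def hit_to_dict(h: SearchHit) -> dict:
    return {
        "track": track_to_dict(h.track),
        "matched_count": h.matched_count,
        "coverage": round(h.coverage, 6),
    }


def segment_to_dict(s: AlignmentSegment) -> dict:
    return {
        "orientation": s.orientation.value,
        "score": s.score,
        "steps": [
            {"query": st.query, "target": st.target, "state": st.state.value}
            for st in s.steps
        ],
    }


def aligned_to_dict(a: AlignedTrack) -> dict:
    return {
        "track": track_to_dict(a.track),
        "segments": [segment_to_dict(s) for s in a.segments],
        "total_score": a.total_score,
        "row": a.row,
    }


def block_to_dict(b: SyntenyBlock) -> dict:
    return {
        "query_chromosome": b.query_chromosome,
        "target_chromosome": b.target_chromosome,
        "target_source": b.target_source,
        "target_genome": b.target_genome,
        "query_span": list(b.query_span),
        "target_span": list(b.target_span),
        "query_bp": list(b.query_bp) if b.query_bp else None,
        "target_bp": list(b.target_bp) if b.target_bp else None,
        "orientation": b.orientation.value,
        "pair_count": b.pair_count,
        "row": b.row,
    }


def macro_track_to_dict(m: MacroTrack) -> dict:
    return {
        "source": m.source,
        "chromosome": m.chromosome,
        "genome": m.genome,
        "distance": round(m.distance, 6),
        "blocks": [block_to_dict(b) for b in m.blocks],
    }


def msa_to_dict(msa: MSA) -> dict:
    return {
        "n_columns": msa.hmm.ncols,
        "medoid_index": msa.medoid_index,
        "assignments": [
            [[state, col] for state, col in asn] for asn in msa.assignments
        ],
    }


def dump_json(payload: dict) -> str:
    return json.dumps(payload, indent=2, sort_keys=True)


def result_envelope(command: str, parameters: dict, results: dict) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "tool": {"name": "syntenic", "version": __version__, "command": command},
        "parameters": parameters,
        "results": results,
    }


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; loadable from YAML."""

    sources: list[dict]
    genes: list[str] = field(default_factory=list)
    intervals: list[dict] = field(default_factory=list)
    neighbors: int = 10
    cluster: ClusterParams = field(default_factory=ClusterParams)
    pseudocount: float = 0.1
    search: SearchParams = field(default_factory=SearchParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    macro: MacroParams = field(default_factory=MacroParams)
    macro_enabled: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            sources=d["sources"],
            genes=list(d.get("genes", [])),
            intervals=list(d.get("intervals", [])),
            neighbors=int(d.get("neighbors", 10)),
            cluster=ClusterParams(**d.get("cluster", {})),
            pseudocount=float(d.get("pseudocount", 0.1)),
            search=SearchParams(**d.get("search", {})),
            scoring=ScoringScheme(**d.get("scoring", {})),
            macro=MacroParams(**d.get("macro", {})),
            macro_enabled=bool(d.get("macro_enabled", True)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls.from_dict(d)
        for src in cfg.sources:
            for key in ("gff3", "families"):
                if not Path(src[key]).exists():
                    raise FileNotFoundError(f"source file {src[key]!r} does not exist")
        return cfg

    def effective_parameters(self) -> dict:
        return {
            "sources": [s["name"] for s in self.sources],
            "genes": self.genes,
            "intervals": self.intervals,
            "neighbors": self.neighbors,
            "cluster": asdict(self.cluster),
            "pseudocount": self.pseudocount,
            "search": asdict(self.search),
            "scoring": asdict(self.scoring),
            "macro": asdict(self.macro),
            "macro_enabled": self.macro_enabled,
            "seed": self.seed,
        }


def load_sources(source_specs: Sequence[dict]) -> list[DataSource]:
    return [
        load_source(
            s["gff3"], s["families"], s["name"], s.get("gene_type", "gene")
        )
        for s in source_specs
    ]


def resolve_gene(sources: Sequence[DataSource], gene_name: str) -> DataSource:
    for src in sources:
        try:
            src.gene_location(gene_name)
            return src
        except NotFoundError:
            continue
    names = ", ".join(s.name for s in sources)
    raise NotFoundError(f"gene {gene_name!r} not found in any source ({names})")


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Query tracks -> clustering -> per-cluster search -> alignment ->
    macrosynteny, as one deterministic JSON-able result."""
    sources = load_sources(config.sources)
    query_tracks: list[Track] = []
    for gene in config.genes:
        src = resolve_gene(sources, gene)
        query_tracks.append(make_query_track(src, gene, config.neighbors))
    for iv in config.intervals:
        src = next(s for s in sources if s.name == iv["source"])
        query_tracks.append(
            make_track_from_interval(src, iv["chromosome"], iv["start"], iv["end"])
        )
    if not query_tracks:
        raise ValueError("configuration defines no queries")

    clusters = cluster_tracks(query_tracks, config.cluster)
    cluster_results = []
    for members in clusters:
        member_tracks = [query_tracks[i] for i in members]
        if len(member_tracks) > 1:
            msa = build_msa(
                [t.family_sequence() for t in member_tracks], config.pseudocount
            )
            reference = consensus(msa)
            msa_json = msa_to_dict(msa)
        else:
            msa = None
            reference = member_tracks[0].family_sequence()
            msa_json = None
        hits = search(sources, member_tracks, config.search)
        aligned = align_all(reference, hits, config.scoring)
        cluster_results.append(
            {
                "members": [track_to_dict(t) for t in member_tracks],
                "msa": msa_json,
                "consensus": list(reference.families),
                "hits": [hit_to_dict(h) for h in hits],
                "alignments": [aligned_to_dict(a) for a in aligned],
            }
        )

    macro_results = []
    if config.macro_enabled:
        seen: set[tuple[str, str]] = set()
        for t in query_tracks:
            key = (t.source, t.chromosome)
            if key in seen:
                continue
            seen.add(key)
            src = next(s for s in sources if s.name == t.source)
            tracks = macrosynteny_tracks(
                src.chromosomes[t.chromosome], sources, config.macro
            )
            macro_results.append(
                {
                    "query_source": t.source,
                    "query_chromosome": t.chromosome,
                    "tracks": [macro_track_to_dict(m) for m in tracks],
                }
            )

    return result_envelope(
        "run",
        config.effective_parameters(),
        {"clusters": cluster_results, "macro": macro_results},
    )


def dotplot_pairs(
    track_a: Track,
    track_b: Track,
    global_mode: bool = False,
    source: Optional[DataSource] = None,
) -> list[dict]:
    """Gene pairs sharing a family between two tracks, for dot plotting.

    Local mode pairs the two tracks; global mode pairs track_a's whole
    chromosome (resolved through ``source``) against track_b.  Pairs carry
    base-pair midpoints for plotting.
    """
    if global_mode:
        if source is None:
            raise ValueError("global mode needs the data source of track_a")
        chrom = source.chromosomes[track_a.chromosome]
        a_genes = list(chrom.genes)
    else:
        a_genes = list(track_a.genes)
    pairs = []
    for ga in a_genes:
        if ga.family is None:
            continue
        for gb in track_b.genes:
            if gb.family == ga.family:
                pairs.append(
                    {
                        "gene_a": ga.name,
                        "gene_b": gb.name,
                        "family": ga.family,
                        "a_midpoint": ga.midpoint,
                        "b_midpoint": gb.midpoint,
                    }
                )
    return pairs
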