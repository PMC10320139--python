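"""Genome-evolution simulator: families of related annotated genomes.

An ancestor genome is generated with a configurable number of chromosomes and
genes; derived genomes are produced by applying recorded rearrangement events
(whole-genome duplication, inversions, deletions, tandem duplications,
translocations) whose ground truth is kept in an :class:`EventLog`.  Replaying
a log on the ancestor reproduces the derived genome exactly, which makes the
log the acceptance surface for recovery tests in every other module.

Gene coordinates are re-laid out deterministically (per-gene lengths are
preserved, intergenic spacing is constant) after each event, since ground
truth lives in gene-index space.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io import write_family_tsv, write_gff3
from .model import Chromosome, DataSource, Gene, SyntenicError, build_data_source


@dataclass
class SimParams:
    """Scale and event rates of one simulated genome family.

    ``n_families=None`` assigns every ancestral gene its own family (the
    uniform-without-replacement limit): family multiplicity then arises only
    from the modeled duplication events.  An integer draws families uniformly
    with replacement from a vocabulary of that size.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    n_families: Optional[int] = None
    orphan_rate: float = 0.05
    mean_gene_length: int = 3000
    mean_intergenic_length: int = 3000
    n_inversions: int = 2
    n_deletions: int = 2
    n_tandem_dups: int = 1
    n_translocations: int = 1
    wgd: bool = False
    min_event_genes: int = 3
    max_event_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "genes_per_chromosome", "n_inversions",
            "n_deletions", "n_tandem_dups", "n_translocations",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.orphan_rate <= 1.0:
            raise ValueError("orphan_rate must be in [0, 1]")
        if self.min_event_genes < 1 or self.max_event_genes < self.min_event_genes:
            raise ValueError("need 1 <= min_event_genes <= max_event_genes")


@dataclass
class EventLog:
    """Ordered record of the rearrangements applied to derive a genome."""

    name: str
    events: list[dict] = field(default_factory=list)
    #: derived gene name -> ancestral gene name it descends from
    origin_of: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "events": self.events, "origin_of": self.origin_of},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        d = json.loads(text)
        return cls(name=d["name"], events=d["events"], origin_of=d["origin_of"])


# internal mutable gene record: (origin gene name, family-or-None, strand, length)
_Record = tuple[str, Optional[str], int, int]


def _records_of(source: DataSource) -> dict[str, list[_Record]]:
    return {
        cname: [(g.name, g.family, g.strand, g.length) for g in chrom.genes]
        for cname, chrom in source.chromosomes.items()
    }


def _layout(
    name: str, records: dict[str, list[_Record]], genome: str, intergenic: int
) -> tuple[list[Chromosome], dict, dict]:
    """Deterministic coordinate layout + renaming; returns (chromosomes,
    family map, derived-name -> origin-name map)."""
    chromosomes = []
    family_map: dict[str, Optional[str]] = {}
    origin_of: dict[str, str] = {}
    for cname in sorted(records):
        genes = []
        pos = 0
        for i, (origin, family, strand, length) in enumerate(records[cname]):
            gname = f"{name}_{cname}_g{i:04d}"
            genes.append(
                Gene(
                    name=gname,
                    chromosome=cname,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                )
            )
            family_map[gname] = family
            origin_of[gname] = origin
            pos += length + intergenic
        chromosomes.append(
            Chromosome(name=cname, genome=name, length=pos, genes=genes)
        )
    return chromosomes, family_map, origin_of


def make_ancestor(params: SimParams, name: str = "ancestor") -> DataSource:
    """Random ancestor genome; fully deterministic given ``params.seed``."""
    rng = np.random.default_rng([params.seed % 2**31, 0xA])
    records: dict[str, list[_Record]] = {}
    counter = 0
    for c in range(params.n_chromosomes):
        cname = f"chr{c + 1}"
        recs: list[_Record] = []
        for _ in range(params.genes_per_chromosome):
            if rng.random() < params.orphan_rate:
                family = None
            elif params.n_families is None:
                family = f"fam{counter:05d}"
            else:
                family = f"fam{int(rng.integers(0, params.n_families)):05d}"
            counter += 1
            strand = 1 if rng.random() < 0.5 else -1
            length = max(200, int(rng.exponential(params.mean_gene_length)))
            recs.append((f"{name}:{cname}:{len(recs)}", family, strand, length))
        records[cname] = recs
    chromosomes, family_map, _ = _layout(
        name, records, name, params.mean_intergenic_length
    )
    return build_data_source(chromosomes, family_map, name)


def apply_events(
    ancestor: DataSource,
    events: list[dict],
    name: str,
    intergenic: int,
) -> tuple[DataSource, dict]:
    """Apply an event list to the ancestor; returns (derived source,
    derived-gene -> ancestral-gene origin map).  Deterministic."""
    records = _records_of(ancestor)
    for ev in events:
        etype = ev["type"]
        if etype == "WGD":
            doubled: dict[str, list[_Record]] = {}
            for cname in sorted(records):
                doubled[cname + "a"] = list(records[cname])
                doubled[cname + "b"] = list(records[cname])
            records = doubled
            continue
        cname = ev["chromosome"]
        if cname not in records:
            raise SyntenicError(f"event on unknown chromosome {cname!r}")
        recs = records[cname]
        if etype == "TRANSLOCATION":
            start, length = ev["start"], ev["length"]
            if start < 0 or start + length > len(recs):
                raise SyntenicError(f"event span outside chromosome {cname!r}")
            moved = recs[start : start + length]
            del recs[start : start + length]
            dest = records[ev["dest_chromosome"]]
            di = min(ev["dest_index"], len(dest))
            dest[di:di] = moved
            continue
        start, length = ev["start"], ev["length"]
        if start < 0 or start + length > len(recs):
            raise SyntenicError(f"event span outside chromosome {cname!r}")
        if etype == "INVERSION":
            recs[start : start + length] = [
                (o, f, -s, ln) for o, f, s, ln in reversed(recs[start : start + length])
            ]
        elif etype == "DELETION":
            del recs[start : start + length]
        elif etype == "TANDEM_DUP":
            recs[start + length : start + length] = list(recs[start : start + length])
        else:
            raise SyntenicError(f"unknown event type {etype!r}")
    chromosomes, family_map, origin_of = _layout(name, records, name, intergenic)
    return build_data_source(chromosomes, family_map, name), origin_of


def derive_genome(
    ancestor: DataSource, params: SimParams, name: str = "derived"
) -> tuple[DataSource, EventLog]:
    """Sample an event list per ``params`` and apply it to the ancestor.

    Events are applied in order: WGD (if any), inversions, deletions, tandem
    duplications, translocations.  Spans are recorded in the gene-index space
    of the chromosome at the time the event is applied.
    """
    rng = np.random.default_rng(
        [params.seed % 2**31, 0xD, zlib.crc32(name.encode()) % 2**31]
    )
    events: list[dict] = []
    # simulate forward on a shadow copy so sampled spans always fit
    records = _records_of(ancestor)
    if params.wgd:
        events.append({"type": "WGD"})
        doubled: dict[str, list[_Record]] = {}
        for cname in sorted(records):
            doubled[cname + "a"] = list(records[cname])
            doubled[cname + "b"] = list(records[cname])
        records = doubled

    def sample_span():
        names = sorted(records)
        weights = np.array([len(records[c]) for c in names], dtype=float)
        if weights.sum() == 0:
            raise SyntenicError("no genes left to rearrange")
        cname = names[int(rng.choice(len(names), p=weights / weights.sum()))]
        n = len(records[cname])
        length = int(
            rng.integers(params.min_event_genes, params.max_event_genes + 1)
        )
        length = min(length, n)
        start = int(rng.integers(0, n - length + 1))
        return cname, start, length

    for _ in range(params.n_inversions):
        cname, start, length = sample_span()
        events.append(
            {"type": "INVERSION", "chromosome": cname, "start": start, "length": length}
        )
        recs = records[cname]
        recs[start : start + length] = [
            (o, f, -s, ln) for o, f, s, ln in reversed(recs[start : start + length])
        ]
    for _ in range(params.n_deletions):
        cname, start, length = sample_span()
        events.append(
            {"type": "DELETION", "chromosome": cname, "start": start, "length": length}
        )
        del records[cname][start : start + length]
    for _ in range(params.n_tandem_dups):
        cname, start, length = sample_span()
        events.append(
            {"type": "TANDEM_DUP", "chromosome": cname, "start": start, "length": length}
        )
        recs = records[cname]
        recs[start + length : start + length] = list(recs[start : start + length])
    for _ in range(params.n_translocations):
        if len(records) < 2:
            break
        cname, start, length = sample_span()
        others = [c for c in sorted(records) if c != cname]
        dest = others[int(rng.integers(0, len(others)))]
        dest_index = int(rng.integers(0, len(records[dest]) + 1))
        events.append(
            {
                "type": "TRANSLOCATION",
                "chromosome": cname,
                "start": start,
                "length": length,
                "dest_chromosome": dest,
                "dest_index": dest_index,
            }
        )
        moved = records[cname][start : start + length]
        del records[cname][start : start + length]
        records[dest][dest_index:dest_index] = moved

    derived, origin_of = apply_events(
        ancestor, events, name, params.mean_intergenic_length
    )
    return derived, EventLog(name=name, events=events, origin_of=origin_of)


def replay(ancestor: DataSource, log: EventLog, intergenic: int = 3000) -> DataSource:
    """Re-apply a recorded event log; reproduces the derived genome exactly
    when the same intergenic spacing is used."""
    derived, _ = apply_events(ancestor, log.events, log.name, intergenic)
    return derived


def emit(
    source: DataSource,
    directory: Union[str, Path],
    log: Optional[EventLog] = None,
) -> dict:
    """Write {name}.gff3, {name}.families.tsv and (optionally)
    {name}.events.json; read-back through the I/O module reproduces the
    in-memory source."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": directory / f"{source.name}.gff3",
        "families": directory / f"{source.name}.families.tsv",
    }
    write_gff3(list(source.chromosomes.values()), paths["gff3"])
    write_family_tsv(source, paths["families"])
    if log is not None:
        paths["events"] = directory / f"{source.name}.events.json"
        paths["events"].write_text(log.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}


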