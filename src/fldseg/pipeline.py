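"""End-to-end orchestration of the reconstruction stages.

``run_all`` executes simulate (optional) -> terminals -> group -> annotate
-> utr -> abundance into a run directory and writes a manifest with
parameters and output checksums; a rerun with the same seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import annotate as an
from . import grouping as gr
from . import io as fio
from . import synthgen as sg
from . import terminals as tm
from . import utr as ut

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline; unknown keys rejected."""

    output_dir: str
    seed: int = 0
    simulate: bool = True
    contigs: str | None = None
    alignments: str | None = None
    adaptor: str = sg.DEFAULT_ADAPTOR
    total_cleaned_reads: int | None = None  # defaults to simulated read count
    # simulation block
    n_genomes: int = 10
    coverage: float = 50.0
    error_rate: float = 0.002
    # terminals block
    window: int = 50
    min_events: int = 3
    enrich: float = 5.0
    max_mismatch: int = 1
    # grouping block
    group_window: int = 30
    group_min_id: float = 0.8
    group_max_offset: int = 5
    # annotation block
    min_aa: int = 60
    # utr block
    utr_link_window: int = 100
    utr_link_step: int = 10
    utr_link_min_id: float = 0.68
    # abundance block
    cluster_min_id: float = 0.97
    map_min_identity: float = 0.97
    map_max_indel: int = 3
    pool_below: float = 0.02

    def __post_init__(self) -> None:
        if not self.simulate and (self.contigs is None or self.alignments is None):
            raise ConfigError("without simulation, contigs and alignments paths are required")
        for name, lo, hi in (
            ("group_min_id", 0.0, 1.01),
            ("cluster_min_id", 0.0, 1.0),
            ("map_min_identity", 0.0, 1.0),
            ("utr_link_min_id", 0.0, 1.0),
            ("pool_below", 0.0, 1.0),
            ("error_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dataclasses.asdict(config)

    if config.simulate:
        cfg = sg.SimConfig(
            n_genomes=config.n_genomes,
            coverage=config.coverage,
            error_rate=config.error_rate,
            adaptor=config.adaptor,
            seed=config.seed,
        )
        genomes = sg.simulate_genomes(cfg)
        reads, truth = sg.simulate_flds_reads(genomes, cfg)
        contigs = sg.segments_as_contigs(genomes)
        alignments = sg.align_reads(reads, truth, contigs)
        fio.write_fasta(contigs, out / "contigs.fasta")
        fio.write_fastq(reads, out / "reads.fastq")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if config.total_cleaned_reads is None:
            config = dataclasses.replace(config, total_cleaned_reads=len(reads))
    else:
        contigs = fio.read_fasta(config.contigs)
        alignments = fio.read_sam(config.alignments)
        if config.total_cleaned_reads is None:
            raise ConfigError("total_cleaned_reads is required when not simulating")

    # terminals
    calls, trimmed = tm.analyze_terminals(
        contigs,
        alignments,
        config.adaptor,
        window=config.window,
        min_events=config.min_events,
        enrich=config.enrich,
        max_mismatch=config.max_mismatch,
    )
    tm.terminal_report(calls).to_csv(out / "terminals.tsv", sep="\t", index=False)
    fio.write_fasta(trimmed, out / "trimmed.fasta")

    # grouping
    signatures = [
        gr.terminal_signature(c, W=config.group_window)
        for c in trimmed
        if len(c.seq) >= 2 * config.group_window
    ]
    sets = gr.group_segments(
        signatures, min_id=config.group_min_id, max_offset=config.group_max_offset
    ) if signatures else []
    pd.DataFrame(
        [
            {"genome_id": s.genome_id, "n_segments": s.n_segments,
             "members": ",".join(s.member_contigs)}
            for s in sets
        ]
    ).to_csv(out / "genomes.tsv", sep="\t", index=False)

    # annotation
    annotations = []
    for seg in trimmed:
        annotations.extend(an.annotate_segment(seg, min_aa=config.min_aa))
    fio.write_gff(
        annotations, out / "annotations.gff3", {c.id: len(c.seq) for c in trimmed}
    )
    with open(out / "proteins.faa", "w") as fh:
        for i, a in enumerate(annotations, start=1):
            fh.write(f">{a.segment_id}|orf{i} {a.start}-{a.end}({a.strand})\n{a.protein}\n")

    # UTR characterization
    stop_rows, trinuc_rows = [], []
    by_seg: dict[str, list] = {}
    for a in annotations:
        by_seg.setdefault(a.segment_id, []).append(a)
    for seg in trimmed:
        smap = ut.stop_codon_map(seg)
        for f, positions in enumerate(smap.frames):
            for p in positions:
                stop_rows.append({"segment_id": seg.id, "frame": f, "pos": p})
        anns = sorted(by_seg.get(seg.id, []), key=lambda x: x.start)
        fwd = [a for a in anns if a.strand == "+"]
        if fwd and fwd[0].start >= 100:
            utr_region = ut.NucSequence(f"{seg.id}_5utr", seg.seq[: fwd[0].start])
            prof = ut.trinuc_profile(utr_region, "utr")
            trinuc_rows.append({"region_id": prof.region_id, "kind": prof.kind,
                                **dict(zip(ut.TRINUCS, prof.trinuc_freq))})
        for a in fwd:
            region = ut.NucSequence(f"{seg.id}_{a.start}", seg.seq[a.start : a.end])
            prof = ut.trinuc_profile(region, "other")
            trinuc_rows.append({"region_id": prof.region_id, "kind": "cds",
                                **dict(zip(ut.TRINUCS, prof.trinuc_freq))})
    pd.DataFrame(stop_rows).to_csv(out / "stops.tsv", sep="\t", index=False)
    pd.DataFrame(trinuc_rows).to_csv(out / "trinuc.tsv", sep="\t", index=False)

    # abundance
    clusters = ab.greedy_cluster(contigs, min_id=config.cluster_min_id)
    lengths = {c.id: len(c.seq) for c in contigs}
    counts = ab.count_fragments(
        alignments, clusters, lengths,
        min_identity=config.map_min_identity, max_indel=config.map_max_indel,
    )
    table = ab.fpkm_table(counts, lengths, config.total_cleaned_reads)
    table.to_csv(out / "abundance.tsv", sep="\t", index=False)
    comp = ab.composition_summary(table, pool_below=config.pool_below)
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)

    manifest = {
        "parameters": params,
        "n_contigs": len(contigs),
        "n_alignments": len(alignments),
        "n_genome_sets": len(sets),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
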