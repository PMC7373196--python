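"""End-to-end pipeline orchestration with a reproducibility manifest.

``simulate`` mode generates a ground-truth library and then analyses it;
``analyze`` mode starts from user-supplied reads (or alignments) and a
reference. All stage outputs are plain text (FASTQ/FASTA/GFF3/BED/bedGraph/
TSV/JSON) so runs are diffable, and ``manifest.json`` records the config
hash, seed, input checksums and the read/cluster/duplex counts at every
stage. A single global seed drives every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import align, clusters, composition, duplexes, overlap, quant
from .features import read_annotation, read_feature_bed
from .genome import Genome
from .simulate import SimulationConfig, simulate

logger = logging.getLogger("dcscan")

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Validated run description; see ``RunConfig.from_file`` for the schema."""

    mode: str  # simulate | analyze
    outdir: str
    seed: int = 0
    genome: str | None = None
    reads: str | None = None
    alignments: str | None = None
    annotation: str | None = None
    adapter: str | None = None
    feature_sets: dict[str, str] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    duplex: dict[str, Any] = field(default_factory=dict)
    comp: dict[str, Any] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if self.mode == "analyze":
            if not self.genome:
                raise ValueError("analyze mode requires the 'genome' path")
            if not self.reads and not self.alignments:
                raise ValueError("analyze mode requires 'reads' or 'alignments'")
            for label, p in (
                ("genome", self.genome),
                ("reads", self.reads),
                ("alignments", self.alignments),
                ("annotation", self.annotation),
                *self.feature_sets.items(),
            ):
                if p and not Path(p).exists():
                    raise ValueError(f"input path for {label!r} does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.__dict__, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the stage graph for the configured mode; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}
    checksums: dict[str, str] = {}

    if config.mode == "simulate":
        sim_conf = SimulationConfig(**{**config.simulation, "seed": config.seed})
        cluster_params = clusters.ClusterParams(**config.cluster) if config.cluster else clusters.ClusterParams()
        logger.info("simulating %d loci", len(sim_conf.locus_plan))
        result = simulate(sim_conf, out_dir=outdir, cluster_params=cluster_params)
        genome = result.genome
        annotation = result.annotation
        reads = result.emitted.reads
        counts["simulated_loci"] = len(result.truth.loci)
        counts["captured_duplexes_truth"] = len(result.truth.captured_products)
    else:
        genome = Genome.from_fasta(config.genome)
        checksums["genome"] = _sha256(Path(config.genome))
        annotation = read_annotation(config.annotation) if config.annotation else []
        cluster_params = clusters.ClusterParams(**config.cluster) if config.cluster else clusters.ClusterParams()
        reads = None

    if config.mode == "analyze" and config.alignments:
        checksums["alignments"] = _sha256(Path(config.alignments))
        alignments = align.load_alignments(config.alignments)
        counts["reads_in"] = len(alignments)
        counts["trimmed"] = len(alignments)
        counts["mapped"] = sum(a.count for a in alignments)
    else:
        if reads is None:
            checksums["reads"] = _sha256(Path(config.reads))
            reads = align.read_sequences(config.reads)
        counts["reads_in"] = len(reads)
        if config.adapter:
            reads, trim_stats = align.trim_adapter(reads, config.adapter)
            counts["trimmed"] = trim_stats.trimmed
            counts["untrimmed"] = trim_stats.untrimmed
            counts["discarded_short"] = trim_stats.discarded
        else:
            counts["trimmed"] = len(reads)
        alignments, map_stats = align.map_exact(reads, genome)
        counts["mapped"] = map_stats.mapped
        counts["multi_mapped"] = map_stats.multi_mapped
        counts["unmapped"] = map_stats.unmapped

    lib = align.library_size(alignments)
    counts["library_size"] = lib
    if lib == 0:
        raise RuntimeError("no reads aligned; nothing to analyse")

    # coverage + bedGraph per reference sequence present
    for chrom in sorted({a.chrom for a in alignments}):
        track = align.build_coverage(
            [a for a in alignments if a.chrom == chrom], genome, chrom=chrom
        )
        align.export_bedgraph(track, outdir / f"coverage.{chrom}")

    # clusters
    called = clusters.call_clusters(alignments, cluster_params, lib)
    clusters.export_clusters(called, outdir / "clusters.bed", outdir / "clusters.tsv")
    counts["clusters"] = len(called)

    # duplexes
    records = duplexes.collapse_unique(alignments, lib)
    dup_kwargs = dict(config.duplex)
    found = duplexes.find_duplexes(records, **dup_kwargs)
    duplexes.export_cleavage_table(found, outdir / "duplexes.tsv", genome=genome)
    duplexes.export_duplex_bed(found, outdir / "duplexes.bed")
    counts["duplexes_per_length"] = duplexes.duplex_length_counts(found)
    counts["duplexes"] = len(found)

    # composition profiles for each standard duplex length
    for L in (21, 22):
        params = composition.CompositionParams(read_length=L, **config.comp)
        try:
            profile = composition.positional_gc(records, genome, params)
        except ValueError:
            continue  # no reads of this length
        composition.export_profile(profile, outdir / f"composition_L{L}.tsv")

    # per-gene quantification
    if annotation:
        gene_counts, intergenic = quant.count_gene_reads(alignments, annotation, lib)
        quant.export_gene_counts(gene_counts, outdir / "gene_counts.tsv")
        counts["genes"] = len(gene_counts)
        counts["intergenic_reads"] = intergenic

    # overlap with external feature sets
    feature_overlaps = {}
    for name, path in config.feature_sets.items():
        fs = read_feature_bed(path, name)
        checksums[f"features:{name}"] = _sha256(Path(path))
        n, _ = overlap.overlap_count(called, fs)
        feature_overlaps[name] = n
    if feature_overlaps:
        counts["cluster_feature_overlaps"] = feature_overlaps

    manifest = {
        "version": VERSION,
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "input_checksums": checksums,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
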