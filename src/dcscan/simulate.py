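"""Ground-truth simulator for p19-captured RNase III products.

The generative model, stage by stage:

1. **Genome** — i.i.d. bases at a chosen GC content (the E. coli K-12
   chromosome is 50.8% GC, the default here).
2. **Loci** — pairs of overlapping sense/antisense transcripts in four
   architectures: ``divergent5`` (5' ends overlap, transcription pointing
   apart), ``convergent3`` (3' ends overlap, pointing together),
   ``full_overlap`` (an annotated antisense gene contained in the sense
   transcript) and ``novel_as`` (the same geometry but the asRNA is absent
   from the annotation). The perfectly paired overlap region is the dsRNA
   substrate.
3. **RNase III digestion** — each dsRNA molecule is cut sequentially 5'->3'
   with jittered spacing around a mode-dependent product length (~14 bp with
   Mg2+, ~21 bp with Mn2+). Both strands are severed 2 nt apart so every
   internal product is a perfect duplex with 2-nt 3' overhangs; the two
   terminal fragments have only one cut end and are flagged non-duplex.
   Candidate cut positions are weighted by ``exp(beta_site * score)`` where
   the score rewards AU-rich 3-nt windows flanking the scissile bonds and
   GC-rich overhang dinucleotides — the enzyme's observed sequence
   preference.
4. **p19 capture** — each duplex is retained with probability proportional
   to a length weight (mass on 21-22 bp) times ``exp(beta_body * bodyGC)``,
   modelling p19's size selection and its subtle preference for GC-rich
   duplex bodies. Terminal fragments are never retained.
5. **Read emission** — per-strand read counts are Poisson with a per-duplex
   lognormal strand bias (cloning bias), sequences are exact genomic
   substrings at Q40, and uniformly placed single-stranded noise reads model
   non-duplex material that escapes the capture step.

Every stage is seeded from the single config seed, so a fixed config yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .align import AlignedRead
from .clusters import ClusterParams, call_clusters
from .composition import CompositionParams
from .features import GeneFeature, write_gff3
from .genome import Genome, revcomp

ARCHITECTURES = ("divergent5", "convergent3", "full_overlap", "novel_as")

# E. coli K-12 chromosomal GC content
DEFAULT_GC = 0.508

# modal duplex product length by divalent cation in the digestion buffer
MODE_PRODUCT_MEAN = {"mg": 14, "mn": 21}


@dataclass
class LocusSpec:
    """One planned overlapping sense/antisense locus.

    ``abundance`` is the expected number of long dsRNA molecules entering
    digestion. Transcript lengths default to the overlap plus a 150-nt
    non-overlapping extension (contained architectures pad the sense
    transcript symmetrically instead).
    """

    architecture: str
    overlap_length: int
    abundance: int
    sense_length: int | None = None
    antisense_length: int | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.overlap_length < 1 or self.abundance < 0:
            raise ValueError("overlap_length must be >= 1 and abundance >= 0")

    def resolved_lengths(self) -> tuple[int, int]:
        ext = 150
        if self.architecture in ("full_overlap", "novel_as"):
            sense = self.sense_length or self.overlap_length + ext
            anti = self.antisense_length or self.overlap_length
            if anti != self.overlap_length:
                raise ValueError(
                    "contained architectures require antisense_length == overlap_length"
                )
            if sense < anti:
                raise ValueError("sense transcript shorter than contained antisense")
        else:
            sense = self.sense_length or self.overlap_length + ext
            anti = self.antisense_length or self.overlap_length + ext
            if min(sense, anti) < self.overlap_length:
                raise ValueError("transcripts shorter than the requested overlap")
        return sense, anti


@dataclass
class SimulationConfig:
    """All knobs of the generative model; see the module docstring."""

    genome_length: int = 100_000
    genome_gc: float = DEFAULT_GC
    locus_plan: list[LocusSpec] = field(default_factory=list)
    digestion_mode: str = "mn"  # mg | mn
    product_length_mean: int | None = None  # default from digestion_mode
    product_length_sd: float = 1.5
    cleavage_preference_strength: float = 2.0  # beta_site
    overhang: int = 2  # 0 emulates blunt-ended (non-RNase III) products
    p19_length_weights: dict[int, float] = field(
        default_factory=lambda: {21: 1.0, 22: 1.0}
    )
    p19_body_gc_coeff: float = 3.0  # beta_body
    strand_bias_sd: float = 0.25
    noise_read_count: int = 0
    seed: int = 0
    chrom_name: str = "sim_chrom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.genome_gc <= 1.0:
            raise ValueError("genome_gc must lie in [0, 1]")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.digestion_mode not in MODE_PRODUCT_MEAN:
            raise ValueError("digestion_mode must be 'mg' or 'mn'")
        if self.product_length_mean is None:
            self.product_length_mean = MODE_PRODUCT_MEAN[self.digestion_mode]
        if self.product_length_mean < 6:
            raise ValueError("product_length_mean must be >= 6")
        if self.overhang < 0:
            raise ValueError("overhang must be >= 0")
        if self.cleavage_preference_strength < 0:
            raise ValueError("cleavage_preference_strength must be >= 0")
        if self.noise_read_count < 0:
            raise ValueError("noise_read_count must be >= 0")
        self.locus_plan = [
            ls if isinstance(ls, LocusSpec) else LocusSpec(**ls)
            for ls in self.locus_plan
        ]
        for i, ls in enumerate(self.locus_plan):
            if ls.overlap_length < self.product_length_mean + 4:
                raise ValueError(
                    f"locus {i}: overlap_length must be >= product_length_mean + 4"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass(frozen=True)
class Locus:
    """A planted locus with its realised coordinates (all 0-based half-open)."""

    index: int
    architecture: str
    chrom: str
    sense: tuple[int, int]  # plus strand
    antisense: tuple[int, int]  # minus strand
    overlap: tuple[int, int]
    abundance: int


@dataclass(frozen=True)
class Product:
    """One digestion fragment of one dsRNA molecule."""

    chrom: str
    plus_start: int
    plus_end: int
    minus_start: int
    minus_end: int
    is_duplex: bool
    locus_index: int

    @property
    def length(self) -> int:
        return self.plus_end - self.plus_start


@dataclass(frozen=True)
class CapturedProduct:
    """A p19-retained duplex, aggregated over molecules."""

    chrom: str
    plus_start: int
    plus_end: int
    minus_start: int
    minus_end: int
    count: int

    @property
    def length(self) -> int:
        return self.plus_end - self.plus_start


@dataclass
class SimulationTruth:
    """Ground truth accumulated across the simulation stages."""

    loci: list[Locus] = field(default_factory=list)
    cut_sites: list[tuple[str, int, int]] = field(default_factory=list)
    products: list[Product] = field(default_factory=list)
    captured_products: list[CapturedProduct] = field(default_factory=list)
    expected_clusters: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stage 1: genome
# ---------------------------------------------------------------------------


def generate_genome(
    length: int, gc: float, seed: int, chrom_name: str = "sim_chrom"
) -> Genome:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        np.array(list("GCAT")),
        size=length,
        p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2],
    )
    return Genome({chrom_name: "".join(bases)})


# ---------------------------------------------------------------------------
# Stage 2: loci
# ---------------------------------------------------------------------------

_LOCUS_MARGIN = 60  # bp kept between loci and from the reference edges


def plant_loci(
    genome: Genome, config: SimulationConfig
) -> tuple[list[GeneFeature], SimulationTruth]:
    """Place the planned loci left to right with fixed margins.

    Returns the gene annotation (the asRNA of a ``novel_as`` locus is, by
    definition, not annotated) and a truth object with the locus geometry.
    Raises a placement error naming the first locus that does not fit.
    """
    chrom = config.chrom_name
    glen = genome.length(chrom)
    truth = SimulationTruth()
    annotation: list[GeneFeature] = []
    cursor = _LOCUS_MARGIN
    for i, spec in enumerate(config.locus_plan):
        s_len, a_len = spec.resolved_lengths()
        ov = spec.overlap_length
        x0 = cursor
        if spec.architecture == "divergent5":
            anti = (x0, x0 + a_len)
            sense = (x0 + a_len - ov, x0 + a_len - ov + s_len)
            overlap = (sense[0], anti[1])
        elif spec.architecture == "convergent3":
            sense = (x0, x0 + s_len)
            anti = (x0 + s_len - ov, x0 + s_len - ov + a_len)
            overlap = (anti[0], sense[1])
        else:  # full_overlap / novel_as: antisense contained in sense
            sense = (x0, x0 + s_len)
            pad = (s_len - ov) // 2
            anti = (x0 + pad, x0 + pad + ov)
            overlap = anti
        right = max(sense[1], anti[1])
        if right + _LOCUS_MARGIN > glen:
            raise ValueError(
                f"locus {i} ({spec.architecture}) does not fit in the genome: "
                f"needs up to position {right + _LOCUS_MARGIN}, length {glen}"
            )
        locus = Locus(i, spec.architecture, chrom, sense, anti, overlap, spec.abundance)
        truth.loci.append(locus)
        annotation.append(
            GeneFeature(
                f"gene_s{i:03d}", chrom, sense[0], sense[1], "+",
                architecture=spec.architecture,
            )
        )
        if spec.architecture != "novel_as":
            annotation.append(
                GeneFeature(
                    f"gene_a{i:03d}", chrom, anti[0], anti[1], "-",
                    architecture=spec.architecture,
                )
            )
        cursor = right + _LOCUS_MARGIN
    return annotation, truth


# ---------------------------------------------------------------------------
# Stage 3: digestion
# ---------------------------------------------------------------------------


def _au_count(seq: str) -> int:
    return seq.count("A") + seq.count("T")


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def _cut_score(ref: str, c: int, overhang: int) -> float:
    """Sequence preference at a candidate cut: AU-rich 3-nt windows on both
    sides of the scissile bonds plus GC-rich overhang, each scaled to [0,1]."""
    left = ref[max(c - 3 - overhang, 0) : c - overhang]
    right = ref[c : c + 3]
    score = (_au_count(left) + _au_count(right)) / 6.0
    if overhang > 0:
        score += _gc_count(ref[c - overhang : c]) / overhang
    return score


def digest_duplexes(
    genome: Genome, truth: SimulationTruth, config: SimulationConfig
) -> SimulationTruth:
    """Digest each locus's dsRNA molecules into short duplex products.

    Walks 5'->3' along the overlap region: inter-cut spacing is
    ``round(Normal(mean, sd))`` clamped to >= 6, and the realised cut is
    drawn among the seven offsets within +-3 of the sampled spacing with
    probability proportional to a triangular jitter prior (peaked at the
    sampled spacing, so the spacing distribution keeps its mode at the
    mode-dependent mean) times ``exp(beta_site * score)``. Each cut severs
    the minus strand ``overhang`` nt to the left of the plus-strand cut, so
    internal products carry the 3' overhang signature at both ends.
    """
    if not truth.loci:
        raise ValueError("plant_loci must run before digestion")
    rng = np.random.default_rng([config.seed, 1])
    ref = genome[config.chrom_name]
    beta = config.cleavage_preference_strength
    oh = config.overhang
    mean, sd = config.product_length_mean, config.product_length_sd
    for locus in truth.loci:
        os_, oe = locus.overlap
        for _ in range(locus.abundance):
            cuts: list[int] = []
            pos = os_
            while True:
                spacing = max(6, int(round(rng.normal(mean, sd))))
                cands = [
                    c
                    for c in range(pos + spacing - 3, pos + spacing + 4)
                    if c - pos >= 6 and os_ + oh <= c <= oe
                ]
                if not cands:
                    break
                # triangular jitter prior: offset j from the sampled spacing
                # gets weight 4-|j|, then sequence preference multiplies in
                w = np.array(
                    [
                        (4 - abs(c - pos - spacing))
                        * math.exp(beta * _cut_score(ref, c, oh))
                        for c in cands
                    ],
                    dtype=float,
                )
                c = int(rng.choice(cands, p=w / w.sum()))
                cuts.append(c)
                pos = c
            # fragments: [os_, cuts[0]), internal duplexes, [cuts[-1], oe)
            bounds = [os_] + cuts + [oe]
            for k in range(len(bounds) - 1):
                a, b = bounds[k], bounds[k + 1]
                if b <= a:
                    continue
                internal = 1 <= k <= len(bounds) - 3
                truth.products.append(
                    Product(
                        locus.chrom, a, b, a - oh, b - oh,
                        is_duplex=internal, locus_index=locus.index,
                    )
                )
            truth.cut_sites.extend(
                (locus.chrom, c, c - oh) for c in cuts
            )
    return truth


# ---------------------------------------------------------------------------
# Stage 4: p19 capture
# ---------------------------------------------------------------------------


def _body_gc(ref: str, start: int, end: int) -> float:
    L = end - start
    body = ref[start + 3 : end - 5]  # positions 4..L-5 (1-based)
    if not body:
        return 0.0
    return _gc_count(body) / len(body)


def p19_capture(
    truth: SimulationTruth, genome: Genome, config: SimulationConfig
) -> SimulationTruth:
    """Retain duplex products by length weight and body-GC preference.

    Retention probability = length_weight(L) * exp(beta_body * bodyGC),
    normalised by the largest attainable weight so it is a proper Bernoulli
    probability regardless of the pool. Non-duplex terminal fragments are
    never retained; lengths absent from the weight map get weight 0.
    """
    if not truth.products:
        truth.captured_products = []
        return truth
    rng = np.random.default_rng([config.seed, 2])
    ref = genome[config.chrom_name]
    weights = config.p19_length_weights
    beta = config.p19_body_gc_coeff
    if not weights or max(weights.values()) <= 0:
        raise ValueError("p19_length_weights must contain a positive weight")
    norm = max(weights.values()) * math.exp(max(beta, 0.0))
    kept: Counter[tuple[str, int, int, int, int]] = Counter()
    for prod in truth.products:
        if not prod.is_duplex:
            continue
        lw = weights.get(prod.length, 0.0)
        if lw <= 0:
            continue
        p = lw * math.exp(beta * _body_gc(ref, prod.plus_start, prod.plus_end)) / norm
        if rng.random() < p:
            kept[
                (prod.chrom, prod.plus_start, prod.plus_end,
                 prod.minus_start, prod.minus_end)
            ] += 1
    truth.captured_products = [
        CapturedProduct(*key, count=n) for key, n in sorted(kept.items())
    ]
    return truth


# ---------------------------------------------------------------------------
# Stage 5: read emission
# ---------------------------------------------------------------------------


@dataclass
class EmittedReads:
    """In-memory view of the emitted library plus its truth alignments."""

    reads: list[tuple[str, str]]  # (name, sequence), read orientation
    duplex_alignments: list[AlignedRead]  # duplex-derived reads only
    noise_alignments: list[AlignedRead]

    @property
    def alignments(self) -> list[AlignedRead]:
        return self.duplex_alignments + self.noise_alignments


def emit_reads(
    truth: SimulationTruth,
    genome: Genome,
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    cluster_params: ClusterParams | None = None,
) -> EmittedReads:
    """Emit sequencing reads from captured duplexes plus background noise.

    Per captured duplex with molecule count ``n`` the two strand read counts
    are ``Poisson(n * b)`` and ``Poisson(n / b)`` with ``log b ~
    Normal(0, strand_bias_sd)`` drawn once per duplex. Noise reads are
    single-stranded, 18-30 nt, uniformly placed. When ``out_dir`` is given,
    writes ``reads.fastq`` (Q40), ``cleavage_sites.tsv`` and
    ``expected_clusters.bed``; ``truth.expected_clusters`` is filled by
    running the cluster caller's window rule on the duplex-derived reads.
    """
    rng = np.random.default_rng([config.seed, 3])
    ref = genome[config.chrom_name]
    chrom = config.chrom_name
    reads: list[tuple[str, str]] = []
    duplex_al: list[AlignedRead] = []
    serial = 0
    for cp in truth.captured_products:
        b = math.exp(rng.normal(0.0, config.strand_bias_sd))
        n_plus = int(rng.poisson(cp.count * b))
        n_minus = int(rng.poisson(cp.count / b))
        plus_seq = ref[cp.plus_start : cp.plus_end]
        minus_seq = revcomp(ref[cp.minus_start : cp.minus_end])
        for _ in range(n_plus):
            reads.append((f"dup_{serial:07d}", plus_seq))
            serial += 1
        for _ in range(n_minus):
            reads.append((f"dup_{serial:07d}", minus_seq))
            serial += 1
        if n_plus:
            duplex_al.append(
                AlignedRead(chrom, cp.plus_start, cp.plus_end, "+", plus_seq, n_plus)
            )
        if n_minus:
            duplex_al.append(
                AlignedRead(chrom, cp.minus_start, cp.minus_end, "-", minus_seq, n_minus)
            )

    noise_al: list[AlignedRead] = []
    glen = len(ref)
    for j in range(config.noise_read_count):
        length = int(rng.integers(18, 31))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = ref[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        reads.append((f"noise_{j:07d}", seq))
        noise_al.append(AlignedRead(chrom, start, start + length, strand, seq))

    # expected clusters under the caller's own window rule, noise excluded
    params = cluster_params or ClusterParams()
    lib = sum(a.count for a in duplex_al) + len(noise_al)
    if duplex_al and lib > 0:
        called = call_clusters(duplex_al, params, library_size=lib)
        truth.expected_clusters = [(c.chrom, c.start, c.end) for c in called]
    else:
        truth.expected_clusters = []

    result = EmittedReads(reads, duplex_al, noise_al)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, out_dir / "reads.fastq")
        write_truth_tables(truth, out_dir)
    return result


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Q40 FASTQ (no simulated sequencing errors)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tables(truth: SimulationTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    with open(out_dir / "cleavage_sites.tsv", "w") as fh:
        fh.write("chrom\tplus_start\tplus_end\tminus_start\tminus_end\tcount\n")
        for cp in truth.captured_products:
            fh.write(
                f"{cp.chrom}\t{cp.plus_start}\t{cp.plus_end}\t"
                f"{cp.minus_start}\t{cp.minus_end}\t{cp.count}\n"
            )
    with open(out_dir / "expected_clusters.bed", "w") as fh:
        for chrom, start, end in truth.expected_clusters:
            fh.write(f"{chrom}\t{start}\t{end}\texpected_cluster\t0\t.\n")


# ---------------------------------------------------------------------------
# End-to-end convenience + calibration fixture generator
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    genome: Genome
    annotation: list[GeneFeature]
    truth: SimulationTruth
    emitted: EmittedReads


def simulate(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    cluster_params: ClusterParams | None = None,
) -> SimulationResult:
    """Run all five stages; optionally write FASTA/GFF3/FASTQ/truth files."""
    genome = generate_genome(
        config.genome_length, config.genome_gc, config.seed, config.chrom_name
    )
    annotation, truth = plant_loci(genome, config)
    digest_duplexes(genome, truth, config)
    p19_capture(truth, genome, config)
    emitted = emit_reads(truth, genome, config, out_dir, cluster_params)
    if out_dir is not None:
        out_dir = Path(out_dir)
        genome.to_fasta(out_dir / "genome.fasta")
        write_gff3(annotation, out_dir / "annotation.gff3")
    return SimulationResult(genome, annotation, truth, emitted)


def plant_composition_reads(
    n: int,
    params: CompositionParams,
    overhang_gc: float = 0.60,
    flank_au: float = 0.60,
    background_gc: float = DEFAULT_GC,
    seed: int = 0,
    chrom_name: str = "calib_chrom",
) -> tuple[Genome, list[AlignedRead]]:
    """Calibration fixture: reads with exactly planted regional composition.

    Builds a synthetic genome of ``n`` concatenated read+flank windows (plus
    spacers) in which overhang positions are G/C with probability
    ``overhang_gc``, cleavage-flank positions are A/T with probability
    ``flank_au`` and all other positions are G/C with probability
    ``background_gc``, then returns plus-strand alignments over the embedded
    reads. Used to verify that the positional profiler recovers planted
    per-region composition, independent of the digestion model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L, F = params.read_length, params.flank
    rmap = params.region_map()
    positions = params.positions
    spacer = 5
    width = L + 2 * F
    chunks: list[str] = []
    alignments: list[AlignedRead] = []
    offset = 0
    gc_bases, au_bases = "GC", "AT"
    for i in range(n):
        window = []
        for p in positions:
            region = rmap[p]
            if region in ("overhang_this_strand", "overhang_partner"):
                p_gc = overhang_gc
            elif region == "cleavage_flank":
                p_gc = 1.0 - flank_au
            else:
                p_gc = background_gc
            pool = gc_bases if rng.random() < p_gc else au_bases
            window.append(pool[int(rng.integers(0, 2))])
        chunk = "".join(window) + "A" * spacer
        start = offset + F
        alignments.append(AlignedRead(chrom_name, start, start + L, "+"))
        chunks.append(chunk)
        offset += width + spacer
    genome = Genome({chrom_name: "".join(chunks)})
    return genome, alignments
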