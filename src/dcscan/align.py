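"""Read preprocessing, exact mapping, strand-specific coverage and profiles.

The mapper here is deliberately exact-match and unique-placement only: the
duplex geometry downstream assumes a read *is* the genomic substring it came
from, and a read whose sequence occurs more than once in the genome (on
either strand) cannot be assigned an unambiguous duplex partner. Reads from
real experiments aligned with a general-purpose aligner can be supplied as
SAM or BED6 instead.

Coordinates are 0-based half-open throughout; 1-based inclusive appears only
in exported report tables.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from scipy import stats

from .genome import Genome, revcomp, VALID_BASES


@dataclass(frozen=True)
class AlignedRead:
    """A strand-aware exact placement of a small-RNA read.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``sequence``
    (optional) is in read orientation, i.e. reverse complemented relative to
    the reference for minus-strand placements. ``count`` carries read
    multiplicity so identical reads can be collapsed before mapping.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match interval length")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CoverageTrack:
    """Per-position, per-strand read coverage over one reference sequence.

    ``plus``/``minus`` are float vectors of the reference length. In
    ``combined`` strand mode both strands were summed into ``plus`` and
    ``minus`` is all zeros.
    """

    chrom: str
    plus: np.ndarray
    minus: np.ndarray
    scale: str = "raw"  # raw | rpm
    library_size: int | None = None
    strand_mode: str = "split"  # split | combined

    def combined(self) -> np.ndarray:
        return self.plus + self.minus

    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())


# ---------------------------------------------------------------------------
# Read I/O and adapter trimming
# ---------------------------------------------------------------------------


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Load (name, sequence) pairs from FASTA/FASTQ, optionally gzipped."""
    path = Path(path)
    name = path.name.lower()
    fmt = "fastq" if name.rstrip(".gz").endswith(("fastq", "fq")) else "fasta"
    if name.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, fmt)]
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


@dataclass
class TrimStats:
    total: int = 0
    trimmed: int = 0
    untrimmed: int = 0  # kept but no adapter match found
    discarded: int = 0  # shorter than min_len after trimming


def trim_adapter(
    reads: Iterable[tuple[str, str]],
    adapter: str,
    min_overlap: int = 3,
    min_len: int = 15,
) -> tuple[list[tuple[str, str]], TrimStats]:
    """Remove a 3' sequencing/cloning adapter by exact prefix matching.

    The suffix starting at the leftmost position where the read matches the
    first ``k >= min_overlap`` bases of the adapter (through the read 3' end,
    or a full internal adapter occurrence) is removed. Reads shorter than
    ``min_len`` after trimming are discarded; reads without any match are
    kept and counted as untrimmed.
    """
    if not adapter:
        raise ValueError("adapter must be a non-empty sequence")
    adapter = adapter.upper()
    out: list[tuple[str, str]] = []
    stats = TrimStats()
    for name, seq in reads:
        stats.total += 1
        seq = seq.upper()
        cut = None
        for i in range(len(seq)):
            m = min(len(adapter), len(seq) - i)
            if m >= min_overlap and seq[i : i + m] == adapter[:m]:
                cut = i
                break
        if cut is None:
            stats.untrimmed += 1
            out.append((name, seq))
        elif cut < min_len:
            stats.discarded += 1
        else:
            stats.trimmed += 1
            out.append((name, seq[:cut]))
    return out, stats


# ---------------------------------------------------------------------------
# Exact mapping
# ---------------------------------------------------------------------------


@dataclass
class MapStats:
    total: int = 0
    mapped: int = 0
    multi_mapped: int = 0
    unmapped: int = 0
    invalid: int = 0  # non-ACGT characters


def _occurrences(haystack: str, needle: str, limit: int = 2) -> list[int]:
    """Start positions of ``needle`` in ``haystack``, at most ``limit`` found."""
    hits: list[int] = []
    pos = haystack.find(needle)
    while pos != -1 and len(hits) < limit:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def map_exact(
    reads: Iterable[tuple[str, str]], genome: Genome
) -> tuple[list[AlignedRead], MapStats]:
    """Place reads that occur exactly once in the genome (both strands jointly).

    A forward occurrence yields a plus-strand placement, a reverse-complement
    occurrence a minus-strand one. Reads occurring zero times or more than
    once across both orientations and all reference sequences are dropped and
    counted. Identical read sequences are looked up once and share a
    placement with summed multiplicity.
    """
    stats = MapStats()
    seq_counts: Counter[str] = Counter()
    for _, seq in reads:
        stats.total += 1
        seq_counts[seq.upper()] += 1

    alignments: list[AlignedRead] = []
    for seq, n in sorted(seq_counts.items()):
        if set(seq) - VALID_BASES:
            stats.invalid += n
            continue
        placements: list[tuple[str, int, str]] = []
        rc = revcomp(seq)
        for chrom in genome:
            ref = genome[chrom]
            for pos in _occurrences(ref, seq):
                placements.append((chrom, pos, "+"))
            for pos in _occurrences(ref, rc):
                placements.append((chrom, pos, "-"))
            if len(placements) > 1:
                break
        if not placements:
            stats.unmapped += n
        elif len(placements) > 1:
            stats.multi_mapped += n
        else:
            chrom, pos, strand = placements[0]
            stats.mapped += n
            alignments.append(
                AlignedRead(chrom, pos, pos + len(seq), strand, seq, count=n)
            )
    alignments.sort(key=lambda a: (a.chrom, a.start, a.end, a.strand))
    return alignments, stats


# ---------------------------------------------------------------------------
# External alignments
# ---------------------------------------------------------------------------


def load_alignments(path: str | Path) -> list[AlignedRead]:
    """Load alignments from SAM (1-based, header required) or BED6 (0-based).

    Unmapped, secondary and supplementary SAM records are skipped; strand
    comes from flag 0x10 (SAM) or column 6 (BED).
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        out: list[AlignedRead] = []
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                strand = "-" if rec.is_reverse else "+"
                out.append(
                    AlignedRead(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        strand,
                    )
                )
        return out
    # BED6
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                chrom, start, end, _name, _score, strand = fields[:6]
                out.append(AlignedRead(chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
    return out


# ---------------------------------------------------------------------------
# Summaries, coverage, normalisation
# ---------------------------------------------------------------------------


def length_histogram(
    items: Sequence[AlignedRead] | Sequence[tuple[str, str]],
) -> dict[int, float]:
    """Read-length distribution as fractions summing to 1, count-weighted."""
    counts: Counter[int] = Counter()
    for item in items:
        if isinstance(item, AlignedRead):
            counts[item.length] += item.count
        else:
            counts[len(item[1])] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot build a length histogram from empty input")
    return {length: n / total for length, n in sorted(counts.items())}


def library_size(alignments: Iterable[AlignedRead]) -> int:
    """Total aligned read count (the RPM denominator)."""
    return sum(a.count for a in alignments)


def build_coverage(
    alignments: Sequence[AlignedRead],
    genome: Genome,
    chrom: str | None = None,
    strand_mode: str = "split",
) -> CoverageTrack:
    """Per-position coverage: position p gains ``count`` for every alignment
    with start <= p < end. ``combined`` mode sums both strands."""
    if strand_mode not in ("split", "combined"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if chrom is None:
        chroms = {a.chrom for a in alignments}
        if len(chroms) > 1:
            raise ValueError("multiple chromosomes present; pass chrom explicitly")
        chrom = chroms.pop() if chroms else next(iter(genome))
    n = genome.length(chrom)
    plus = np.zeros(n)
    minus = np.zeros(n)
    for a in alignments:
        if a.chrom != chrom:
            continue
        if a.end > n:
            raise ValueError(f"alignment [{a.start},{a.end}) beyond {chrom} length {n}")
        target = plus if a.strand == "+" else minus
        target[a.start : a.end] += a.count
    if strand_mode == "combined":
        plus = plus + minus
        minus = np.zeros(n)
    return CoverageTrack(chrom, plus, minus, strand_mode=strand_mode)


def rpm_scale(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale a raw track to reads per million aligned reads."""
    if track.scale == "rpm":
        raise ValueError("track is already RPM-scaled")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    f = 1e6 / library_size
    return CoverageTrack(
        track.chrom,
        track.plus * f,
        track.minus * f,
        scale="rpm",
        library_size=library_size,
        strand_mode=track.strand_mode,
    )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def _runs(values: np.ndarray) -> Iterable[tuple[int, int, float]]:
    """Maximal runs of equal value as (start, end, value), zeros omitted."""
    n = len(values)
    if n == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        v = values[s]
        if v != 0:
            yield int(s), int(e), float(v)


def export_bedgraph(track: CoverageTrack, path: str | Path) -> list[Path]:
    """Write the track as bedGraph (0-based half-open, equal-value runs merged).

    Split tracks produce ``<path>.plus.bedgraph`` and ``<path>.minus.bedgraph``;
    combined tracks a single ``<path>.bedgraph``. Returns the paths written.
    """
    path = Path(path)
    written: list[Path] = []
    if track.strand_mode == "combined":
        parts = [("", track.plus)]
    else:
        parts = [(".plus", track.plus), (".minus", track.minus)]
    for suffix, values in parts:
        out = path.with_name(path.name + suffix + ".bedgraph")
        with open(out, "w") as fh:
            fh.write(f'track type=bedGraph name="{track.chrom}{suffix}"\n')
            for s, e, v in _runs(values):
                fh.write(f"{track.chrom}\t{s}\t{e}\t{v:g}\n")
        written.append(out)
    return written


def import_bedgraph(
    plus_path: str | Path, minus_path: str | Path | None, length: int
) -> CoverageTrack:
    """Rebuild a CoverageTrack from bedGraph file(s) written by export_bedgraph."""

    def load(p: str | Path) -> tuple[str | None, np.ndarray]:
        values = np.zeros(length)
        chrom = None
        with open(p) as fh:
            for line in fh:
                if line.startswith(("track", "#", "browser")) or not line.strip():
                    continue
                c, s, e, v = line.split("\t")
                chrom = c
                values[int(s) : int(e)] = float(v)
        return chrom, values

    chrom_p, plus = load(plus_path)
    if minus_path is None:
        return CoverageTrack(chrom_p or "", plus, np.zeros(length), strand_mode="combined")
    chrom_m, minus = load(minus_path)
    return CoverageTrack(chrom_p or chrom_m or "", plus, minus, strand_mode="split")


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------


def compare_profiles(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    start: int,
    end: int,
) -> tuple[float, float]:
    """Pearson correlation of combined-strand coverage over ``[start, end)``.

    Returns ``(r, p)`` with a two-sided p-value from the t distribution with
    n-2 degrees of freedom. Requires >= 3 positions and nonzero variance in
    both profiles.
    """
    if end - start < 3:
        raise ValueError("region must span at least 3 positions")
    a = track_a.combined()[start:end]
    b = track_b.combined()[start:end]
    if len(a) != end - start or len(b) != end - start:
        raise ValueError("region exceeds track bounds")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance in region")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
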