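"""Positional nucleotide-composition profiling around cleavage products.

Reads of a fixed length L are profiled position by position together with
their 10-nt genomic flanks, all in the read's own 5'->3' orientation.
Positions are 1-based within the read (1..L); flank positions are negative
upstream (-10..-1, no position 0) and L+1..L+10 downstream. Modelling the
RNase III double cut onto this frame partitions the positions into:

* ``body`` — central paired positions 4..L-5 (4..17 for L=22, 4..16 for
  L=21), where the p19 capture step shows its GC preference;
* ``overhang_this_strand`` — the read's own 2-nt 3' overhang, {L-1, L};
* ``overhang_partner`` — the partner strand's overhang seen in the upstream
  flank, {-2, -1};
* ``cleavage_flank`` — four 3-nt windows straddling the two scissile bonds,
  {-5..-3}, {1..3}, {L-4..L-2} and {L+1..L+3}, where RNase III prefers
  AU-rich sequence (half of these positions lie outside the read);
* ``background`` — the remaining flank positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedRead
from .duplexes import UniqueReadRecord
from .genome import Genome

REGIONS = (
    "body",
    "overhang_this_strand",
    "overhang_partner",
    "cleavage_flank",
    "background",
)


@dataclass
class CompositionParams:
    """Profile geometry for one read length.

    ``read_length`` is the duplex-strand length L (21 or 22) and ``flank``
    the number of genomic bases profiled on each side.
    """

    read_length: int = 22
    flank: int = 10

    def __post_init__(self) -> None:
        if self.read_length not in range(18, 31):
            raise ValueError("read_length must be within 18..30")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def positions(self) -> list[int]:
        """Profiled positions in order: -flank..-1, 1..L+flank (no 0)."""
        L, F = self.read_length, self.flank
        return list(range(-F, 0)) + list(range(1, L + F + 1))

    def region_map(self) -> dict[int, str]:
        """Region label for every profiled position (an exact partition)."""
        L = self.read_length
        labels: dict[int, str] = {}
        flank_windows = set()
        for w in ((-5, -3), (1, 3), (L - 4, L - 2), (L + 1, L + 3)):
            flank_windows.update(range(w[0], w[1] + 1))
        for p in self.positions:
            if 4 <= p <= L - 5:
                labels[p] = "body"
            elif p in (L - 1, L):
                labels[p] = "overhang_this_strand"
            elif p in (-2, -1):
                labels[p] = "overhang_partner"
            elif p in flank_windows:
                labels[p] = "cleavage_flank"
            else:
                labels[p] = "background"
        return labels

    def region_positions(self, region: str) -> list[int]:
        rmap = self.region_map()
        return [p for p in self.positions if rmap[p] == region]

    def body_slice(self) -> slice:
        """Slice of a length-L read string covering body positions 4..L-5."""
        return slice(3, self.read_length - 5)


@dataclass
class CompositionProfile:
    """Per-position GC fractions over -F..L+F for a set of L-mers."""

    params: CompositionParams
    gc: dict[int, float]
    n_sequences: int
    weighting: str  # unique | abundance

    def region_summary(self) -> dict[str, float]:
        """Mean GC fraction over each region's positions."""
        rmap = self.params.region_map()
        out: dict[str, list[float]] = {r: [] for r in REGIONS}
        for p, v in self.gc.items():
            out[rmap[p]].append(v)
        return {r: float(np.mean(v)) for r, v in out.items() if v}

    def to_frame(self) -> pd.DataFrame:
        rmap = self.params.region_map()
        return pd.DataFrame(
            {
                "position": self.params.positions,
                "gc_fraction": [self.gc[p] for p in self.params.positions],
                "region": [rmap[p] for p in self.params.positions],
                "n": self.n_sequences,
            }
        )


def _oriented_window(
    genome: Genome, rec: UniqueReadRecord | AlignedRead, flank: int
) -> str | None:
    """Read plus flanks in read orientation; None if flanks leave the reference."""
    lo, hi = rec.start - flank, rec.end + flank
    if lo < 0 or hi > genome.length(rec.chrom):
        return None
    return genome.fetch(rec.chrom, lo, hi, rec.strand)


def positional_gc(
    records: Sequence[UniqueReadRecord] | Sequence[AlignedRead],
    genome: Genome,
    params: CompositionParams,
    weighting: str = "unique",
    min_rpm: float = 0.0,
) -> CompositionProfile:
    """Per-position GC fraction across reads of length ``params.read_length``.

    Under ``unique`` weighting every record counts once; under ``abundance``
    each record is weighted by its read count. Records of other lengths, or
    below ``min_rpm`` (for records carrying an ``rpm`` field), or whose
    flanks would extend beyond the reference, are skipped and counted.
    """
    if weighting not in ("unique", "abundance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    L, F = params.read_length, params.flank
    width = L + 2 * F
    gc_sum = np.zeros(width)
    total_weight = 0.0
    n_used = 0
    n_skipped = 0
    for rec in records:
        if rec.end - rec.start != L:
            n_skipped += 1
            continue
        if min_rpm > 0 and getattr(rec, "rpm", np.inf) < min_rpm:
            n_skipped += 1
            continue
        window = _oriented_window(genome, rec, F)
        if window is None:
            n_skipped += 1
            continue
        w = float(getattr(rec, "count", 1)) if weighting == "abundance" else 1.0
        arr = np.frombuffer(window.encode(), dtype=np.uint8)
        gc_sum += w * ((arr == ord("G")) | (arr == ord("C")))
        total_weight += w
        n_used += 1
    if n_used == 0:
        raise ValueError("no sequences of the requested length were included")
    fractions = gc_sum / total_weight
    gc = {p: float(fractions[i]) for i, p in enumerate(params.positions)}
    return CompositionProfile(params, gc, n_used, weighting)


def region_summary(
    profile: CompositionProfile,
) -> dict[str, float]:
    """Mean GC per region of an existing profile (convenience wrapper)."""
    return profile.region_summary()


def body_gc_values(
    records: Sequence[UniqueReadRecord] | Sequence[AlignedRead],
    genome: Genome,
    params: CompositionParams,
) -> np.ndarray:
    """Per-sequence GC fraction over body positions 4..L-5."""
    L = params.read_length
    sl = params.body_slice()
    vals = []
    for rec in records:
        if rec.end - rec.start != L:
            continue
        seq = genome.fetch(rec.chrom, rec.start, rec.end, rec.strand)
        body = seq[sl]
        vals.append((body.count("G") + body.count("C")) / len(body))
    return np.asarray(vals)


def compare_body_gc(
    set_a: Sequence[UniqueReadRecord] | Sequence[AlignedRead],
    set_b: Sequence[UniqueReadRecord] | Sequence[AlignedRead],
    genome: Genome,
    params: CompositionParams,
) -> tuple[float, float]:
    """Difference in mean body GC between two read sets, with a two-sided
    Mann-Whitney U p-value on the per-sequence body GC values.

    Returns ``(delta_mean, p_value)`` where ``delta_mean`` is mean(a) -
    mean(b).
    """
    a = body_gc_values(set_a, genome, params)
    b = body_gc_values(set_b, genome, params)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least 2 sequences of length L")
    delta = float(a.mean() - b.mean())
    if np.ptp(np.concatenate([a, b])) == 0:
        return delta, 1.0  # all values tied: no evidence of a difference
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return delta, float(res.pvalue)


def export_profile(profile: CompositionProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def export_body_gc(
    records: Sequence[UniqueReadRecord] | Sequence[AlignedRead],
    genome: Genome,
    params: CompositionParams,
    path: str | Path,
) -> None:
    vals = body_gc_values(records, genome, params)
    pd.DataFrame({"body_gc": vals}).to_csv(path, sep="\t", index=False)
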