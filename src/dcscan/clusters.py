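"""Small dsRNA read-cluster calling.

A cluster is a genomic region holding at least ``min_reads`` read 5' ends
within some 200-bp window, with windows evaluated at every base offset. Reads
are localised by their 5' end (cleavage products are anchored by the cut that
created them), which is why reported cluster spans can be much narrower than
the window — a hot spot of a few dozen coordinates can clear a 2,000-read
threshold on its own. Both strands count toward the threshold; sense and
antisense totals are reported per cluster afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import AlignedRead


@dataclass
class ClusterParams:
    """Window size and abundance threshold for cluster calling.

    Exactly one of ``min_reads`` (raw read count, default 2000) and
    ``min_rpm`` may be set; ``min_rpm`` is converted with the library size at
    call time. ``merge_gap`` allows joining qualifying-window runs separated
    by at most that many offsets.
    """

    window: int = 200
    min_reads: int | None = 2000
    min_rpm: float | None = None
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if (self.min_reads is None) == (self.min_rpm is None):
            raise ValueError("set exactly one of min_reads / min_rpm")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")

    def threshold(self, library_size: int) -> float:
        if self.min_reads is not None:
            return float(self.min_reads)
        return self.min_rpm * library_size / 1e6


@dataclass
class Cluster:
    """A called dsRNA cluster: the tight span of contributing read 5' ends."""

    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    total_reads: int
    total_rpm: float
    sense_reads: int
    antisense_reads: int
    peak_window_reads: int

    @property
    def coords_1based(self) -> tuple[int, int]:
        """1-based inclusive coordinates for report tables."""
        return self.start + 1, self.end


def call_clusters(
    alignments: Sequence[AlignedRead],
    params: ClusterParams,
    library_size: int,
) -> list[Cluster]:
    """Call clusters on one reference; returns them sorted by RPM descending.

    Every maximal run of qualifying window offsets (allowing gaps of at most
    ``merge_gap``) becomes one cluster; its interval is the tight span of the
    5' ends inside the run's windows.
    """
    if not alignments:
        return []
    chroms = sorted({a.chrom for a in alignments})
    threshold = params.threshold(library_size)
    clusters: list[Cluster] = []
    for chrom in chroms:
        clusters.extend(
            _call_one_chrom(
                [a for a in alignments if a.chrom == chrom],
                chrom,
                params,
                threshold,
                library_size,
            )
        )
    clusters.sort(key=lambda c: (-c.total_rpm, c.chrom, c.start))
    for i, c in enumerate(clusters, start=1):
        c.id = f"C-{i}"
    return clusters


def _call_one_chrom(
    alignments: Sequence[AlignedRead],
    chrom: str,
    params: ClusterParams,
    threshold: float,
    library_size: int,
) -> list[Cluster]:
    w = params.window
    ends5 = np.array([a.five_prime for a in alignments])
    counts = np.array([a.count for a in alignments])
    strands = np.array([a.strand == "+" for a in alignments])
    hi = int(ends5.max()) + 1

    # per-position 5'-end counts, then window sums at every offset via cumsum
    per_pos = np.zeros(hi + w, dtype=np.int64)
    np.add.at(per_pos, ends5, counts)
    csum = np.concatenate(([0], np.cumsum(per_pos)))
    # window starting at offset o covers [o, o+w)
    window_counts = csum[w:] - csum[:-w]  # offsets 0 .. hi-1
    qualifying = np.flatnonzero(window_counts >= threshold)
    if qualifying.size == 0:
        return []

    # maximal runs of qualifying offsets, joining gaps <= merge_gap
    breaks = np.flatnonzero(np.diff(qualifying) > params.merge_gap + 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [qualifying.size - 1]))

    clusters: list[Cluster] = []
    for rs, re_ in zip(run_starts, run_ends):
        o_min, o_max = int(qualifying[rs]), int(qualifying[re_])
        # reads whose 5' end lies in any qualifying window of this run
        in_run = (ends5 >= o_min) & (ends5 < o_max + w)
        run_ends5 = ends5[in_run]
        run_counts = counts[in_run]
        total = int(run_counts.sum())
        sense = int(run_counts[strands[in_run]].sum())
        clusters.append(
            Cluster(
                id="",
                chrom=chrom,
                start=int(run_ends5.min()),
                end=int(run_ends5.max()) + 1,
                total_reads=total,
                total_rpm=total * 1e6 / library_size,
                sense_reads=sense,
                antisense_reads=total - sense,
                peak_window_reads=int(window_counts[o_min : o_max + 1].max()),
            )
        )
    return clusters


def rank_deciles(clusters: Sequence[Cluster]) -> dict[str, int]:
    """Assign clusters to abundance deciles 1 (top 10% by RPM) .. 10.

    Group sizes differ by at most one; the most abundant deciles take the
    larger size when the count is not divisible by 10. Ties in RPM are broken
    by genomic coordinate so the assignment is deterministic.
    """
    if not clusters:
        raise ValueError("cannot rank an empty cluster list")
    ordered = sorted(clusters, key=lambda c: (-c.total_rpm, c.chrom, c.start))
    n = len(ordered)
    base, extra = divmod(n, 10)
    out: dict[str, int] = {}
    i = 0
    for decile in range(1, 11):
        size = base + (1 if decile <= extra else 0)
        for c in ordered[i : i + size]:
            out[c.id] = decile
        i += size
    return out


def export_clusters(
    clusters: Sequence[Cluster], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write clusters as BED6+2 and as a 1-based report table."""
    with open(bed_path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t{c.total_rpm:.1f}\t.\t"
                f"{c.sense_reads}\t{c.antisense_reads}\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write(
            "cluster_id\tchrom\tstart_1based\tend_1based\ttotal_reads\t"
            "total_rpm\tsense_reads\tantisense_reads\tpeak_window_reads\n"
        )
        for c in clusters:
            s1, e1 = c.coords_1based
            fh.write(
                f"{c.id}\t{c.chrom}\t{s1}\t{e1}\t{c.total_reads}\t"
                f"{c.total_rpm:.1f}\t{c.sense_reads}\t{c.antisense_reads}\t"
                f"{c.peak_window_reads}\n"
            )
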