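"""Detection of in vivo RNase III cleavage signatures.

RNase III cuts the two strands of a double-stranded RNA two nucleotides
apart, so each excised product is a perfect duplex carrying 2-nt 3'
overhangs at both ends. On the genome this means a plus-strand read at
``[a, a+L)`` pairs with a minus-strand read at ``[a-2, a+L-2)``: the two
plus bases at ``[a+L-2, a+L)`` are the plus strand's 3' overhang and the two
at ``[a-2, a)`` (read on the minus strand) are its partner's. Finding such
pairs among unique, abundance-filtered 21/22-nt reads recovers the cleavage
sites that produced them.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignedRead
from .genome import Genome

OVERHANG = 2  # nt, the RNase III signature offset between paired strands


@dataclass(frozen=True)
class UniqueReadRecord:
    """One distinct read placement with its collapsed abundance."""

    chrom: str
    start: int
    end: int
    strand: str
    count: int
    rpm: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DuplexSite:
    """A perfect small-RNA duplex with 2-nt 3' overhangs at both ends."""

    chrom: str
    plus_start: int  # plus read [plus_start, plus_start + length)
    length: int
    plus_rpm: float
    minus_rpm: float

    @property
    def plus_interval(self) -> tuple[int, int]:
        return self.plus_start, self.plus_start + self.length

    @property
    def minus_interval(self) -> tuple[int, int]:
        return self.plus_start - OVERHANG, self.plus_start + self.length - OVERHANG

    @property
    def paired_region(self) -> tuple[int, int]:
        return self.plus_start, self.plus_start + self.length - OVERHANG

    @property
    def overhang_right(self) -> tuple[int, int]:
        """Genomic interval of the plus strand's 3' overhang."""
        return self.plus_start + self.length - OVERHANG, self.plus_start + self.length

    @property
    def overhang_left(self) -> tuple[int, int]:
        """Genomic interval of the minus strand's 3' overhang."""
        return self.plus_start - OVERHANG, self.plus_start


def collapse_unique(
    alignments: Iterable[AlignedRead], library_size: int
) -> list[UniqueReadRecord]:
    """Merge identical placements, summing counts and computing RPM."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    counts: Counter[tuple[str, int, int, str]] = Counter()
    for a in alignments:
        counts[(a.chrom, a.start, a.end, a.strand)] += a.count
    return [
        UniqueReadRecord(chrom, start, end, strand, n, n * 1e6 / library_size)
        for (chrom, start, end, strand), n in sorted(counts.items())
    ]


def find_duplexes(
    records: Sequence[UniqueReadRecord],
    lengths: Iterable[int] = (21, 22),
    min_rpm: float = 1.0,
    min_rpm_strict: bool = False,
    require_equal_length: bool = True,
) -> list[DuplexSite]:
    """Pair plus/minus unique reads into perfect 2-nt-overhang duplexes.

    A duplex is emitted for every plus record ``[a, a+L)`` and minus record
    ``[a-2, a+L-2)`` with both lengths in ``lengths`` and both abundances at
    or above ``min_rpm`` (strictly above with ``min_rpm_strict``). With
    ``require_equal_length`` both strands must be the same length L; without
    it the partner may have any admissible length anchored at ``a-2``.
    Pairs whose minus interval would start before the reference are skipped.
    """
    lengths = set(lengths)
    if not lengths or not lengths <= set(range(18, 31)):
        raise ValueError("duplex lengths must be within 18..30")

    def passes(rpm: float) -> bool:
        return rpm > min_rpm if min_rpm_strict else rpm >= min_rpm

    minus_by_key: dict[tuple[str, int], list[UniqueReadRecord]] = defaultdict(list)
    for r in records:
        if r.strand == "-" and r.length in lengths and passes(r.rpm):
            minus_by_key[(r.chrom, r.start)].append(r)

    out: list[DuplexSite] = []
    for r in records:
        if r.strand != "+" or r.length not in lengths or not passes(r.rpm):
            continue
        if r.start - OVERHANG < 0:
            continue
        for m in minus_by_key.get((r.chrom, r.start - OVERHANG), []):
            if require_equal_length:
                if m.end != r.end - OVERHANG:  # same L, exact 2-nt offset
                    continue
            elif abs(m.length - r.length) > 1:
                # exploratory mixed mode: left anchor still offset by 2,
                # right-end overhang allowed to be 1-3 nt (21/22 pairs)
                continue
            out.append(DuplexSite(r.chrom, r.start, r.length, r.rpm, m.rpm))
    out.sort(key=lambda d: (d.chrom, d.plus_start, d.length))
    return out


def duplex_length_counts(duplexes: Sequence[DuplexSite]) -> dict[int, int]:
    """Number of duplexes per duplex length (21 vs 22 in the standard run)."""
    return dict(sorted(Counter(d.length for d in duplexes).items()))


def export_cleavage_table(
    duplexes: Sequence[DuplexSite],
    path: str | Path,
    genome: Genome | None = None,
) -> None:
    """Write one row per duplex with 1-based inclusive per-strand coordinates.

    When a genome is supplied the two overhang dinucleotides are included
    (plus-strand genomic sequence).
    """
    rows = []
    for d in duplexes:
        ps, pe = d.plus_interval
        ms, me = d.minus_interval
        row = {
            "chrom": d.chrom,
            "plus_start_1based": ps + 1,
            "plus_end_1based": pe,
            "minus_start_1based": ms + 1,
            "minus_end_1based": me,
            "length": d.length,
            "plus_rpm": d.plus_rpm,
            "minus_rpm": d.minus_rpm,
        }
        if genome is not None:
            ol, oh = d.overhang_left, d.overhang_right
            row["overhang_left_seq"] = genome.fetch(d.chrom, *ol)
            row["overhang_right_seq"] = genome.fetch(d.chrom, *oh)
        rows.append(row)
    columns = [
        "chrom",
        "plus_start_1based",
        "plus_end_1based",
        "minus_start_1based",
        "minus_end_1based",
        "length",
        "plus_rpm",
        "minus_rpm",
    ]
    if genome is not None:
        columns += ["overhang_left_seq", "overhang_right_seq"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def load_cleavage_table(path: str | Path) -> list[DuplexSite]:
    """Read back a table written by :func:`export_cleavage_table`."""
    df = pd.read_csv(path, sep="\t")
    return [
        DuplexSite(
            str(r.chrom),
            int(r.plus_start_1based) - 1,
            int(r.length),
            float(r.plus_rpm),
            float(r.minus_rpm),
        )
        for r in df.itertuples()
    ]


def export_duplex_bed(duplexes: Sequence[DuplexSite], path: str | Path) -> None:
    """BED12-style track: one record spanning both strands, two blocks."""
    with open(path, "w") as fh:
        for i, d in enumerate(duplexes, start=1):
            ms, _ = d.minus_interval
            _, pe = d.plus_interval
            span = pe - ms
            fh.write(
                f"{d.chrom}\t{ms}\t{pe}\tduplex_{i}\t0\t.\t{ms}\t{pe}\t0,0,0\t"
                f"2\t{d.length},{d.length}\t0,{span - d.length}\n"
            )
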