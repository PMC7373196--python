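"""Gene annotation and generic feature-set containers with GFF3/BED I/O.

Only the minimal slice of GFF3 used here — ``gene`` features with ``ID=`` and
an optional ``architecture=`` attribute — is read and written; arbitrary GFF3
hierarchies are out of scope. BED input is 0-based half-open, GFF3 1-based
inclusive, converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene: 0-based half-open interval with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "gene"
    architecture: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureSet:
    """A named set of genomic intervals or points for overlap statistics."""

    name: str
    intervals: list[tuple[str, int, int, str | None]]
    kind: str = "interval"  # interval | point

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "point"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        for chrom, start, end, _strand in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval [{start},{end}) on {chrom}")
            if self.kind == "point" and end != start + 1:
                raise ValueError("point features must have end = start + 1")

    def __len__(self) -> int:
        return len(self.intervals)


def write_gff3(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.architecture:
                attrs += f";architecture={g.architecture}"
            fh.write(
                f"{g.chrom}\tdcscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genes.append(
                GeneFeature(
                    gene_id=attr.get("ID", f"gene_{lineno}"),
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    biotype=attr.get("biotype", "gene"),
                    architecture=attr.get("architecture"),
                )
            )
    return genes


def read_gene_bed6(path: str | Path) -> list[GeneFeature]:
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneFeature(name, chrom, int(start), int(end), strand))
    return genes


def read_annotation(path: str | Path) -> list[GeneFeature]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise BED6."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    return read_gene_bed6(path)


def read_feature_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """BED3/BED6 intervals as a FeatureSet (points when every interval is 1 bp)."""
    intervals: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            intervals.append((chrom, start, end, strand))
    kind = (
        "point"
        if intervals and all(e == s + 1 for _, s, e, _ in intervals)
        else "interval"
    )
    return FeatureSet(name or Path(path).stem, intervals, kind)


def read_tss_tsv(path: str | Path, name: str | None = None) -> FeatureSet:
    """Two-column (chrom, 1-based position) TSV of TSS points."""
    intervals: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            p = int(pos) - 1
            intervals.append((chrom, p, p + 1, None))
    return FeatureSet(name or Path(path).stem, intervals, kind="point")


def write_feature_bed(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, strand in features.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{features.name}\t0\t{strand or '.'}\n")
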