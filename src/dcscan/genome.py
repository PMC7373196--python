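"""Reference-genome container and small sequence utilities.

Small bacterial references (and the simulator's synthetic genomes) fit
comfortably in memory as plain strings, which keeps exact-match lookups and
flank extraction trivial and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``; 0.0 for an empty string."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class Genome:
    """An ordered set of named nucleotide sequences over {A,C,G,T}.

    Parameters
    ----------
    records
        Mapping of sequence name to uppercase nucleotide string. Insertion
        order is preserved and names must be unique (enforced by ``dict``).
    """

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("genome must contain at least one sequence")
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-ACGT characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def length(self, name: str) -> int:
        return len(self.records[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def fetch(self, name: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` (0-based half-open) on the given strand.

        Minus-strand sequences are reverse complemented, i.e. returned in the
        5'->3' orientation of the minus-strand transcript.
        """
        seq = self.records[name]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {name!r} "
                f"(length {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.records.items()
        ]
        SeqIO.write(recs, str(path), "fasta")
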