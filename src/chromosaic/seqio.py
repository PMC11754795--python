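"""Shared sequence utilities and FASTA/BED readers and writers.

Conventions enforced at every file boundary:

- coordinates are 0-based, half-open ``[start, end)``;
- FASTA sequences are uppercased on read and wrapped at 80 columns on write;
- BED output is sorted by (chrom, start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    Sequences are uppercased. Duplicate record names and empty files are
    errors: downstream painting and synteny logic keys on unique names.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as uppercase FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s.upper()), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class BedRecord:
    """One BED4 interval: 0-based half-open, with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative BED coordinate: {self}")
        if self.end <= self.start:
            raise ValueError(f"BED end <= start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read BED4; records are returned sorted (with a warning if re-ordered)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED4 line with {len(fields)} fields: {line!r}")
            records.append(BedRecord(fields[0], int(fields[1]), int(fields[2]), fields[3]))
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    if ordered != records:
        logger.warning("BED input %s was not sorted; sorting on read", path)
    return ordered


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
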