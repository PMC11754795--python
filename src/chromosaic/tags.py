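"""Ancestry-diagnostic k-mer tags: discovery on panels, exact matching on
assemblies.

A diagnostic tag is a canonical k-mer (lexicographically smaller of the
forward and reverse-complement spellings) that occurs in at least
``min_group_freq`` of its own group's panel sequences and in no sequence of
any other group, on either strand. Tag density along an assembly is the
painting signal; matching is exact (no mismatches, no sketching), and
windows containing N produce neither tags nor hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import canonical, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagConfig:
    """k-mer length (odd, so no k-mer is its own reverse complement),
    minimum within-group panel frequency, and multimapping policy."""

    k: int = 31
    min_group_freq: float = 1.0
    max_hits: int | None = None
    discard_multimapping: bool = False

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if not (0.0 < self.min_group_freq <= 1.0):
            raise ValueError(f"min_group_freq must be in (0, 1], got {self.min_group_freq}")


@dataclass(frozen=True)
class DiagnosticTag:
    sequence: str  # canonical form, length k
    group: str
    frequency: float  # fraction of own-group panel sequences containing it


@dataclass(frozen=True)
class TagHit:
    tag: str
    group: str
    chrom: str
    start: int  # 0-based
    strand: str  # '+' if the forward substring is the canonical spelling


def _sequence_kmers(seq: str, k: int) -> set[str]:
    """Canonical k-mers of one sequence; windows containing N are skipped."""
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        out.add(canonical(window))
    return out


def discover_tags(
    panels: Mapping[str, Sequence[str]], cfg: TagConfig | None = None
) -> list[DiagnosticTag]:
    """Find group-specific canonical k-mers across >= 2 panels.

    A k-mer is diagnostic of group g iff its within-g panel frequency is at
    least ``cfg.min_group_freq`` and it occurs in zero sequences of every
    other group. Output sorted by (group, sequence).
    """
    cfg = cfg or TagConfig()
    if len(panels) < 2:
        raise ValueError("tag specificity needs at least 2 groups")
    per_seq_kmers: dict[str, list[set[str]]] = {}
    for group, seqs in panels.items():
        if not seqs:
            raise ValueError(f"empty panel for group {group!r}")
        per_seq_kmers[group] = [_sequence_kmers(s, cfg.k) for s in seqs]
    union: dict[str, set[str]] = {g: set().union(*ks) for g, ks in per_seq_kmers.items()}

    tags: list[DiagnosticTag] = []
    for group, kmer_sets in per_seq_kmers.items():
        others: set[str] = set()
        for g, u in union.items():
            if g != group:
                others |= u
        candidates = union[group] - others
        n = len(kmer_sets)
        for kmer in candidates:
            freq = sum(kmer in ks for ks in kmer_sets) / n
            if freq >= cfg.min_group_freq:
                tags.append(DiagnosticTag(kmer, group, freq))
    tags.sort(key=lambda t: (t.group, t.sequence))
    return tags


def match_tags(
    assembly: Mapping[str, str],
    tags: Iterable[DiagnosticTag],
    cfg: TagConfig | None = None,
) -> list[TagHit]:
    """Exact occurrences of tags on either strand of an assembly.

    Each locus is reported once with the forward-strand start coordinate;
    strand is '+' when the forward substring equals the tag's canonical
    spelling. With ``discard_multimapping`` (or ``max_hits``), tags hitting
    more loci than allowed are dropped entirely.
    """
    cfg = cfg or TagConfig()
    tags = list(tags)
    if not assembly or all(len(s) == 0 for s in assembly.values()):
        raise ValueError("empty assembly")
    if not tags:
        return []
    ks = {len(t.sequence) for t in tags}
    if ks != {cfg.k}:
        raise ValueError(f"tag lengths {sorted(ks)} do not match configured k={cfg.k}")
    index: dict[str, DiagnosticTag] = {t.sequence: t for t in tags}

    hits: list[TagHit] = []
    k = cfg.k
    for chrom in sorted(assembly):
        seq = assembly[chrom].upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            tag = index.get(window)
            if tag is not None:
                hits.append(TagHit(tag.sequence, tag.group, chrom, i, "+"))
                continue
            tag = index.get(revcomp(window))
            if tag is not None:
                hits.append(TagHit(tag.sequence, tag.group, chrom, i, "-"))

    max_hits = 1 if cfg.discard_multimapping else cfg.max_hits
    if max_hits is not None:
        counts: dict[str, int] = {}
        for h in hits:
            counts[h.tag] = counts.get(h.tag, 0) + 1
        dropped = {t for t, c in counts.items() if c > max_hits}
        if dropped:
            logger.info("dropping %d multimapping tags", len(dropped))
        hits = [h for h in hits if h.tag not in dropped]
    hits.sort(key=lambda h: (h.chrom, h.start, h.tag))
    return hits


def write_tags_tsv(tags: Iterable[DiagnosticTag], path: str | Path) -> None:
    pd.DataFrame([t.__dict__ for t in tags]).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path: str | Path) -> list[DiagnosticTag]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "group": str})
    return [DiagnosticTag(r.sequence, r.group, float(r.frequency)) for r in df.itertuples()]


def write_hits_tsv(hits: Iterable[TagHit], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[TagHit]:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "group": str, "chrom": str, "strand": str})
    return [TagHit(r.tag, r.group, r.chrom, int(r.start), r.strand) for r in df.itertuples()]
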