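"""Trio-based marker phasing, haplotype-specific tags, contig parsing.

The phasing follows standard Mendelian trio logic: a child heterozygote is
phased when the parents' genotypes force the origin of exactly one allele
(an allele absent from one parent must have come from the other).
Haplotype 1 is, by convention, the parent-1-derived haplotype. Phased
markers seed haplotype-specific k-mer tags (the k-mer centred on each
marker, built on the haplotype's own allele — and on the alleles of any
other phased markers inside the same window); contigs are then assigned to
H1/H2 by the same dominance rule as ancestry painting, and contigs without
a call are left unassigned (to be carried in both haplotype assemblies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .painting import PaintingConfig, assign_ancestry
from .seqio import canonical
from .tags import DiagnosticTag

logger = logging.getLogger(__name__)

H1, H2, UNASSIGNED = "H1", "H2", "unassigned"


@dataclass(frozen=True)
class Genotype:
    """One biallelic call: unordered allele pair at (chrom, pos)."""

    chrom: str
    pos: int
    alleles: tuple[str, str]

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    def has(self, allele: str) -> bool:
        return allele in self.alleles


@dataclass(frozen=True)
class PhasedMarker:
    chrom: str
    pos: int
    h1_allele: str  # allele on the parent-1-derived haplotype
    h2_allele: str
    source: str = "trio"  # trio | map | unphased

    def __post_init__(self) -> None:
        if self.h1_allele == self.h2_allele:
            raise ValueError(f"phased marker with identical alleles at {self.chrom}:{self.pos}")


def phase_markers_from_trio(
    child: Sequence[Genotype],
    parent1: Sequence[Genotype],
    parent2: Sequence[Genotype],
) -> tuple[list[PhasedMarker], list[Genotype]]:
    """Phase child heterozygotes against the parents.

    Returns (phased markers, Mendelian-inconsistent sites). A site phases
    when exactly one assignment of the child's two alleles to (from-parent1,
    from-parent2) is compatible with the parental genotypes; sites
    incompatible under every assignment are flagged and excluded; sites
    absent from both parents are skipped with a warning.
    """
    p1 = {(g.chrom, g.pos): g for g in parent1}
    p2 = {(g.chrom, g.pos): g for g in parent2}
    phased: list[PhasedMarker] = []
    inconsistent: list[Genotype] = []
    for g in child:
        if not g.is_het:
            continue
        key = (g.chrom, g.pos)
        if key not in p1 and key not in p2:
            logger.warning("site %s:%d missing from both parents; skipped", g.chrom, g.pos)
            continue
        a, b = g.alleles
        # transmission (x from parent1, y from parent2) is compatible when
        # each parent carries the allele it transmits (unknown parent: any)
        compatible = []
        for x, y in ((a, b), (b, a)):
            ok1 = key not in p1 or p1[key].has(x)
            ok2 = key not in p2 or p2[key].has(y)
            if ok1 and ok2:
                compatible.append((x, y))
        if not compatible:
            inconsistent.append(g)
        elif len(compatible) == 1:
            x, y = compatible[0]
            phased.append(PhasedMarker(g.chrom, g.pos, x, y, "trio"))
        # both orders compatible -> uninformative, left unphased
    return phased, inconsistent


def build_haplotype_tags(
    markers: Sequence[PhasedMarker],
    reference: Mapping[str, str],
    k: int = 31,
) -> tuple[set[str], set[str]]:
    """Canonical k-mers centred on each phased marker, per haplotype.

    Both haplotype sequences are materialised locally (reference with each
    haplotype's alleles substituted), so tags near adjacent phased markers
    carry that haplotype's alleles at every covered site. Markers closer
    than (k-1)/2 to a contig end are skipped with a warning; tags arising
    in both sets are removed from both.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    flank = (k - 1) // 2
    by_chrom: dict[str, list[PhasedMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)

    h1_tags: set[str] = set()
    h2_tags: set[str] = set()
    for chrom, ms in by_chrom.items():
        if chrom not in reference:
            raise KeyError(f"marker chromosome {chrom!r} not in reference")
        ref = reference[chrom]
        hap_seqs = {}
        for hap in (1, 2):
            seq = list(ref.upper())
            for m in ms:
                allele = m.h1_allele if hap == 1 else m.h2_allele
                if len(allele) != 1:
                    raise ValueError(f"only SNP markers supported, got {allele!r}")
                seq[m.pos] = allele
            hap_seqs[hap] = "".join(seq)
        for m in sorted(ms, key=lambda m: m.pos):
            if m.pos < flank or m.pos + flank >= len(ref):
                logger.warning("marker %s:%d too close to contig end; skipped", chrom, m.pos)
                continue
            lo = m.pos - flank
            h1_tags.add(canonical(hap_seqs[1][lo : lo + k]))
            h2_tags.add(canonical(hap_seqs[2][lo : lo + k]))
    shared = h1_tags & h2_tags
    return h1_tags - shared, h2_tags - shared


def haplotype_tag_objects(h1_tags: set[str], h2_tags: set[str]) -> list[DiagnosticTag]:
    """Package haplotype tag sets for tags.match_tags / painting."""
    out = [DiagnosticTag(s, H1, 1.0) for s in sorted(h1_tags)]
    out += [DiagnosticTag(s, H2, 1.0) for s in sorted(h2_tags)]
    return out


@dataclass(frozen=True)
class ContigAssignment:
    contig: str
    h1_hits: int
    h2_hits: int
    verdict: str  # H1 | H2 | unassigned


def assign_contigs(
    contig_counts: Mapping[str, tuple[int, int]],
    min_hits: int = 5,
    ratio: float = 0.75,
) -> list[ContigAssignment]:
    """Dominance-rule verdicts from per-contig (H1, H2) tag-hit counts.

    Ties and low-evidence contigs are unassigned; the caller places those
    in both haplotype assemblies.
    """
    cfg = PaintingConfig(window=1, min_hits=min_hits, ratio=ratio)
    out = []
    for contig in sorted(contig_counts):
        c1, c2 = contig_counts[contig]
        label = assign_ancestry({H1: c1, H2: c2}, cfg)
        verdict = label if label in (H1, H2) else UNASSIGNED
        out.append(ContigAssignment(contig, c1, c2, verdict))
    return out
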