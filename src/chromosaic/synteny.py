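"""Collinear synteny blocks, reference-mediated ortholog groups, dot plots.

Similarity search is not performed here: the module consumes a best-hit
table (one best hit per gene, ties pre-resolved) and chains hits into
maximal collinear blocks by dynamic programming under a rank-gap limit.
Blocks computed against a shared reference are associated across assemblies
when strictly more than ``min_shared`` (default 20) reference genes occur in
both, and genes shared between mutually associated blocks form ortholog
groups (at most one member per assembly). Groups can then be filtered to an
ancestry region of a focal assembly — e.g. only genes painted with the
unknown-ancestor label — before phylogenetic analysis and Ks dating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import BedRecord

logger = logging.getLogger(__name__)

MIN_SHARED_GENES = 20  # association needs STRICTLY more than this


@dataclass(frozen=True)
class GeneAnchor:
    """A gene's position in one assembly: rank = order index along its
    chromosome (0-based, strictly increasing), midpoint in bp."""

    gene: str
    assembly: str
    chrom: str
    rank: int
    midpoint: int
    strand: str = "+"


@dataclass(frozen=True)
class SyntenyBlock:
    """Maximal collinear chain of anchor pairs between two assemblies.

    ``pairs`` is ordered by the A-side rank; orientation '+' means B-side
    ranks increase along the chain, '-' means they decrease. When built
    against a reference, side A is the reference.
    """

    assembly_a: str
    assembly_b: str
    chrom_a: str
    chrom_b: str
    pairs: tuple[tuple[GeneAnchor, GeneAnchor], ...]
    orientation: str

    @property
    def gene_count(self) -> int:
        return len(self.pairs)

    @property
    def a_genes(self) -> frozenset[str]:
        return frozenset(a.gene for a, _ in self.pairs)

    def member_of(self, ref_gene: str) -> GeneAnchor | None:
        for a, b in self.pairs:
            if a.gene == ref_gene:
                return b
        return None


def chain_blocks(
    pairs: Sequence[tuple[GeneAnchor, GeneAnchor]],
    max_gap: int = 10,
    min_block: int = 5,
) -> list[SyntenyBlock]:
    """Chain best-hit anchor pairs into non-overlapping collinear blocks.

    Dynamic-programming longest collinear chain: ranks strictly monotone on
    both sides and each step's combined rank displacement (A-side plus
    B-side) at most ``max_gap``, extracting chains best-first; every anchor joins at most one block and blocks
    shorter than ``min_block`` are discarded. Deterministic: ties break on
    (+ before -, then leftmost A-side start).
    """
    for side in (0, 1):
        seen: dict[tuple[str, str], int] = {}
        for p in pairs:
            anchor = p[side]
            key = (anchor.assembly, anchor.gene)
            if key in seen:
                raise ValueError(f"duplicate gene {anchor.gene!r} in assembly {anchor.assembly!r}")
            seen[key] = 1

    by_chrom_pair: dict[tuple[str, str], list[tuple[GeneAnchor, GeneAnchor]]] = {}
    for a, b in pairs:
        by_chrom_pair.setdefault((a.chrom, b.chrom), []).append((a, b))

    blocks: list[SyntenyBlock] = []
    for (chrom_a, chrom_b), group in sorted(by_chrom_pair.items()):
        remaining = sorted(group, key=lambda p: p[0].rank)
        while True:
            best = _best_chain(remaining, max_gap)
            if best is None or len(best[0]) < min_block:
                break
            chain, orient = best
            a0 = chain[0][0]
            blocks.append(
                SyntenyBlock(a0.assembly, chain[0][1].assembly, chrom_a, chrom_b, tuple(chain), orient)
            )
            used = {id(p) for p in chain}
            remaining = [p for p in remaining if id(p) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.pairs[0][0].rank, b.chrom_b))
    return blocks


def _best_chain(
    pairs: list[tuple[GeneAnchor, GeneAnchor]], max_gap: int
) -> tuple[list[tuple[GeneAnchor, GeneAnchor]], str] | None:
    """Longest collinear chain over ``pairs`` (sorted by A rank), trying both
    orientations; O(n^2) DP, adequate for anchor tables at desk scale."""
    n = len(pairs)
    if n == 0:
        return None
    best_chain: list[tuple[GeneAnchor, GeneAnchor]] | None = None
    best_key: tuple[int, int, int] | None = None  # (-len, orient_order, start_rank)
    for orient_order, orient in enumerate("+-"):
        length = [1] * n
        back: list[int | None] = [None] * n
        for i in range(n):
            ai, bi = pairs[i]
            for j in range(i):
                aj, bj = pairs[j]
                da = ai.rank - aj.rank
                db = bi.rank - bj.rank if orient == "+" else bj.rank - bi.rank
                if not (da > 0 and db > 0 and da + db <= max_gap):
                    continue
                if length[j] + 1 > length[i]:
                    length[i] = length[j] + 1
                    back[i] = j
        i_best = max(range(n), key=lambda i: (length[i], -pairs[i][0].rank))
        chain = []
        i: int | None = i_best
        while i is not None:
            chain.append(pairs[i])
            i = back[i]
        chain.reverse()
        key = (-len(chain), orient_order, chain[0][0].rank)
        if best_key is None or key < best_key:
            best_key = key
            best_chain = chain
            best_orient = orient
    assert best_chain is not None
    if len(best_chain) == 1:
        best_orient = "+"
    return best_chain, best_orient


def associate_blocks(
    blocks_x: Sequence[SyntenyBlock],
    blocks_y: Sequence[SyntenyBlock],
    min_shared: int = MIN_SHARED_GENES,
) -> list[tuple[SyntenyBlock, SyntenyBlock, int]]:
    """Associate reference-side blocks of two assemblies.

    A pair is associated iff STRICTLY more than ``min_shared`` reference
    genes occur in both blocks (orientation is not considered). Association
    is per block pair; no transitive closure.
    """
    out = []
    for bx in blocks_x:
        for by in blocks_y:
            shared = len(bx.a_genes & by.a_genes)
            if shared > min_shared:
                out.append((bx, by, shared))
    return out


@dataclass(frozen=True)
class OrthologGroup:
    ref_gene: str
    members: Mapping[str, str]  # assembly -> gene id (<=1 per assembly)


def build_ortholog_groups(
    blocks_by_assembly: Mapping[str, Sequence[SyntenyBlock]],
    min_shared: int = MIN_SHARED_GENES,
    complete_occupancy: bool = False,
) -> list[OrthologGroup]:
    """Ortholog groups from reference-vs-assembly block sets.

    For each reference gene, each assembly contributes the gene paired with
    it in that assembly's blocks; the group keeps members whose blocks are
    mutually associated (> ``min_shared`` shared reference genes for every
    assembly pair carrying the gene). A reference gene mapped to two
    different genes of one assembly is a conflict: the group is dropped with
    a warning. ``complete_occupancy`` keeps only groups with a member in
    every requested assembly.
    """
    assemblies = sorted(blocks_by_assembly)
    # ref gene -> assembly -> (member gene, block)
    membership: dict[str, dict[str, tuple[str, SyntenyBlock]]] = {}
    conflicts: set[str] = set()
    for asm in assemblies:
        for block in blocks_by_assembly[asm]:
            for ref_anchor, member_anchor in block.pairs:
                slot = membership.setdefault(ref_anchor.gene, {})
                if asm in slot and slot[asm][0] != member_anchor.gene:
                    conflicts.add(ref_anchor.gene)
                slot[asm] = (member_anchor.gene, block)
    if conflicts:
        logger.warning("dropping %d ortholog groups with conflicting members", len(conflicts))

    assoc_cache: dict[tuple[int, int], bool] = {}

    def associated(b1: SyntenyBlock, b2: SyntenyBlock) -> bool:
        key = (id(b1), id(b2))
        if key not in assoc_cache:
            assoc_cache[key] = len(b1.a_genes & b2.a_genes) > min_shared
        return assoc_cache[key]

    groups: list[OrthologGroup] = []
    for ref_gene in sorted(membership):
        if ref_gene in conflicts:
            continue
        slot = membership[ref_gene]
        asms = sorted(slot)
        if any(
            not associated(slot[x][1], slot[y][1])
            for i, x in enumerate(asms)
            for y in asms[i + 1 :]
        ):
            continue
        if complete_occupancy and set(asms) != set(assemblies):
            continue
        groups.append(OrthologGroup(ref_gene, {a: slot[a][0] for a in asms}))
    return groups


def filter_groups_by_ancestry(
    groups: Sequence[OrthologGroup],
    focal_anchors: Mapping[str, GeneAnchor],
    segments: Sequence[BedRecord],
    target_label: str,
    focal_assembly: str,
) -> list[OrthologGroup]:
    """Keep groups whose focal-assembly member's midpoint lies in a segment
    carrying ``target_label`` (half-open membership); groups without a focal
    member are dropped."""
    target = [s for s in segments if s.label == target_label]
    out = []
    for g in groups:
        member = g.members.get(focal_assembly)
        if member is None or member not in focal_anchors:
            continue
        anchor = focal_anchors[member]
        if any(
            s.chrom == anchor.chrom and s.start <= anchor.midpoint < s.end for s in target
        ):
            out.append(g)
    return out


def dotplot_data(
    hits: Iterable[tuple[GeneAnchor, GeneAnchor]],
) -> pd.DataFrame:
    """Best-hit dot-plot points: one row per hit at (reference midpoint,
    target midpoint), grouped by chromosome pair."""
    rows = [
        {
            "ref_chrom": a.chrom,
            "ref_pos": a.midpoint,
            "target_chrom": b.chrom,
            "target_pos": b.midpoint,
            "gene": a.gene,
        }
        for a, b in hits
    ]
    df = pd.DataFrame(rows, columns=["ref_chrom", "ref_pos", "target_chrom", "target_pos", "gene"])
    return df.sort_values(["ref_chrom", "target_chrom", "ref_pos"], ignore_index=True)


def blocks_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        {
            "assembly_a": b.assembly_a,
            "assembly_b": b.assembly_b,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "gene_count": b.gene_count,
            "a_start_rank": b.pairs[0][0].rank,
            "a_end_rank": b.pairs[-1][0].rank,
        }
        for b in blocks
    ]
    return pd.DataFrame(rows)
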