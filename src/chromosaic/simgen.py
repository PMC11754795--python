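"""Synthetic genomes with known truth: panels, mosaics, trios, rearrangements.

Everything downstream of this module (tag discovery, painting, haplotype
parsing, synteny, Ks dating, branch support) is exercised on data generated
here, so every generator is a pure function of (spec, seed) and emits its own
ground truth:

- :func:`simulate_ancestral_groups` evolves sequence panels for several
  ancestral groups down a clocklike tree (branch lengths in years) under a
  Jukes--Cantor substitution process at a per-year rate, default the Musaceae
  synonymous rate 4.5e-9;
- :func:`build_mosaic_genome` concatenates donor slices into a hybrid
  chromosome and emits the truth segments (BED-style, 0-based half-open);
- :func:`apply_rearrangement` applies inversions and reciprocal
  translocations, tracking an exact per-base coordinate map;
- :func:`simulate_trio` draws recombinant gametes from two diploid parents
  with a per-base phase truth;
- :func:`sample_gene_pairs` draws ortholog codon-alignment pairs whose
  synonymous sites diverge with expectation 2*T*rate, the input for testing
  the NG86 -> median Ks -> clock-dating chain.

Read-level artefacts (FASTQ, sequencing error) and indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from . import molevo
from .seqio import BedRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed offsets for deriving independent child streams from one seed, so
# adding a generator call never perturbs another's draws
_STREAM = {
    "root": 0,
    "branch": 1,
    "mosaic": 2,
    "trio": 3,
    "genes": 4,
}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM[stream], index]))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _jc_mutate(seq: np.ndarray, years: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes--Cantor branch: exact transition probabilities per site."""
    p_change = 0.75 * -np.expm1(-4.0 / 3.0 * rate * years)
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    if hit.any():
        # uniform over the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


@dataclass(frozen=True)
class GroupPhylogenySpec:
    """Clocklike phylogeny of ancestral groups for panel simulation.

    ``newick`` gives the rooted topology with branch lengths in YEARS and
    leaf labels naming the groups; ``rate`` is the per-year substitution
    rate (default: Musaceae synonymous rate). Each group's panel holds
    ``n_seqs_per_group`` sequences diverged ``within_group_years`` below the
    group ancestor. ``codon_structured`` requires length % 3 == 0.
    """

    newick: str
    length: int = 200_000
    rate: float = molevo.MUSACEAE_SYN_RATE
    n_seqs_per_group: int = 2
    within_group_years: float = 1.0e5
    codon_structured: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.codon_structured and self.length % 3:
            raise ValueError("codon-structured length must be a multiple of 3")
        tree = self.tree()
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise ValueError("at least 2 groups are required")
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate group names in tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    @property
    def groups(self) -> list[str]:
        return [l.taxon.label for l in self.tree().leaf_node_iter()]


def simulate_ancestral_groups(
    spec: GroupPhylogenySpec,
) -> tuple[dict[str, list[str]], dendropy.Tree]:
    """Evolve per-group sequence panels down the spec's tree.

    Returns ``(panels, tree)`` where ``panels[group]`` is a list of
    sequences. Expected divergence between tips separated by total path
    length L years is the Jukes--Cantor transform of ``L * rate``;
    sister groups at depth T are expected at ``2 * T * rate`` substitutions
    per site. Deterministic given ``spec.seed``.
    """
    tree = spec.tree()
    root_seq = np.frombuffer(
        random_sequence(spec.length, _rng(spec.seed, "root")).encode(), dtype="S1"
    )
    root_codes = np.searchsorted(_BASES, root_seq).astype(np.int64)

    panels: dict[str, list[str]] = {}
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_codes}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node is tree.seed_node:
            seq = states[id(node)]
        else:
            parent_seq = states[id(node.parent_node)]
            rng = _rng(spec.seed, "branch", i)
            seq = _jc_mutate(parent_seq, node.edge.length or 0.0, spec.rate, rng)
            states[id(node)] = seq
        if node.is_leaf():
            group = node.taxon.label
            panel = []
            for j in range(spec.n_seqs_per_group):
                rng = _rng(spec.seed, "branch", 10_000 + 100 * i + j)
                tip = _jc_mutate(seq, spec.within_group_years, spec.rate, rng)
                panel.append(_BASES[tip].tobytes().decode())
            panels[group] = panel
    return panels, tree


@dataclass(frozen=True)
class MosaicSpec:
    """Recipe for one mosaic chromosome: ordered donor segments.

    ``segments`` is a list of ``(length_bp, donor_group, donor_hap_index)``.
    Consecutive donor slices are taken at the segment's own chromosome
    offset, so the mosaic looks like a recombinant of homologous donors.
    """

    chrom: str
    segments: Sequence[tuple[int, str, int]]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("mosaic needs at least one segment")
        for length, group, hap in self.segments:
            if length <= 0:
                raise ValueError(f"segment length must be positive, got {length}")
            if hap < 0:
                raise ValueError(f"haplotype index must be >= 0, got {hap}")

    @property
    def total_length(self) -> int:
        return sum(s[0] for s in self.segments)


@dataclass(frozen=True)
class MosaicTruth:
    """Ground truth emitted by the generators, used as test oracle."""

    segments: tuple[BedRecord, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[BedRecord]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            if segs[0].start != 0:
                raise ValueError(f"truth does not start at 0 on {chrom}")
            for a, b in zip(segs, segs[1:]):
                if a.end != b.start:
                    raise ValueError(f"truth gap/overlap on {chrom}: {a} vs {b}")

    def chrom_length(self, chrom: str) -> int:
        return max(s.end for s in self.segments if s.chrom == chrom)

    def label_at(self, chrom: str, pos: int) -> str:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.label
        raise KeyError(f"{chrom}:{pos} outside truth")


def build_mosaic_genome(
    panels: Mapping[str, Sequence[str]], spec: MosaicSpec
) -> tuple[dict[str, str], MosaicTruth]:
    """Concatenate donor slices into a mosaic chromosome with truth BED.

    Each segment of ``spec`` copies ``panels[group][hap]`` over the interval
    the segment occupies on the mosaic, emulating recombinant inheritance
    from homologous donor chromosomes.
    """
    parts: list[str] = []
    truth: list[BedRecord] = []
    offset = 0
    for length, group, hap in spec.segments:
        if group not in panels:
            raise KeyError(f"donor group {group!r} not in panels {sorted(panels)}")
        donors = panels[group]
        if hap >= len(donors):
            raise IndexError(f"group {group!r} has no haplotype {hap}")
        donor = donors[hap]
        if offset + length > len(donor):
            raise ValueError(
                f"segment [{offset},{offset + length}) exceeds donor "
                f"{group!r}/{hap} length {len(donor)}"
            )
        parts.append(donor[offset : offset + length])
        truth.append(BedRecord(spec.chrom, offset, offset + length, group))
        offset += length
    return {spec.chrom: "".join(parts)}, MosaicTruth(tuple(truth))


# ---------------------------------------------------------------------------
# rearrangements


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class ReciprocalTranslocation:
    """Exchange of the distal parts of two chromosomes at the breakpoints."""

    chrom_a: str
    breakpoint_a: int
    chrom_b: str
    breakpoint_b: int


@dataclass(frozen=True)
class RearrangementSpec:
    """Ordered rearrangement events; coordinates are 0-based half-open and
    refer to the chromosome state at the time the event is applied."""

    events: Sequence[Inversion | ReciprocalTranslocation]


@dataclass(frozen=True)
class _Piece:
    src_chrom: str
    src_start: int
    src_end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


class CoordinateMap:
    """Bijective base-level map between source and rearranged assemblies.

    Internally a piecewise-affine list of source intervals per destination
    chromosome; ``forward`` maps source coordinates to the rearranged
    assembly, ``inverse`` maps back, and forward . inverse is the identity
    on every retained base.
    """

    def __init__(self, pieces: Mapping[str, Sequence[_Piece]]):
        self._pieces = {c: list(ps) for c, ps in pieces.items()}

    def intervals(self) -> list[tuple[str, int, int, str, int, int, str]]:
        """Rows of (src_chrom, src_start, src_end, dst_chrom, dst_start,
        dst_end, strand)."""
        rows = []
        for dst_chrom, pieces in self._pieces.items():
            offset = 0
            for p in pieces:
                rows.append(
                    (p.src_chrom, p.src_start, p.src_end, dst_chrom, offset, offset + p.length, p.strand)
                )
                offset += p.length
        return rows

    def forward(self, chrom: str, pos: int) -> tuple[str, int, str]:
        for src_chrom, s0, s1, dst_chrom, d0, d1, strand in self.intervals():
            if src_chrom == chrom and s0 <= pos < s1:
                if strand == "+":
                    return dst_chrom, d0 + (pos - s0), "+"
                return dst_chrom, d0 + (s1 - 1 - pos), "-"
        raise KeyError(f"source base {chrom}:{pos} not retained")

    def inverse(self, chrom: str, pos: int) -> tuple[str, int, str]:
        for src_chrom, s0, s1, dst_chrom, d0, d1, strand in self.intervals():
            if dst_chrom == chrom and d0 <= pos < d1:
                if strand == "+":
                    return src_chrom, s0 + (pos - d0), "+"
                return src_chrom, s1 - 1 - (pos - d0), "-"
        raise KeyError(f"destination base {chrom}:{pos} not mapped")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("src_chrom\tsrc_start\tsrc_end\tdst_chrom\tdst_start\tdst_end\tstrand\n")
            for row in self.intervals():
                fh.write("\t".join(map(str, row)) + "\n")


def _split_pieces(pieces: list[_Piece], at: int) -> tuple[list[_Piece], list[_Piece]]:
    """Split a piece list at destination coordinate ``at``."""
    left: list[_Piece] = []
    right: list[_Piece] = []
    offset = 0
    for p in pieces:
        if offset + p.length <= at:
            left.append(p)
        elif offset >= at:
            right.append(p)
        else:
            cut = at - offset
            if p.strand == "+":
                left.append(_Piece(p.src_chrom, p.src_start, p.src_start + cut, "+"))
                right.append(_Piece(p.src_chrom, p.src_start + cut, p.src_end, "+"))
            else:
                left.append(_Piece(p.src_chrom, p.src_end - cut, p.src_end, "-"))
                right.append(_Piece(p.src_chrom, p.src_start, p.src_end - cut, "-"))
        offset += p.length
    return left, right


def _flip(pieces: list[_Piece]) -> list[_Piece]:
    flip = {"+": "-", "-": "+"}
    return [
        _Piece(p.src_chrom, p.src_start, p.src_end, flip[p.strand]) for p in reversed(pieces)
    ]


def apply_rearrangement(
    assembly: Mapping[str, str], spec: RearrangementSpec
) -> tuple[dict[str, str], CoordinateMap]:
    """Apply inversions / reciprocal translocations; return new assembly and
    the exact base-level coordinate map. Total base count is conserved;
    inverted intervals are reverse-complemented. Chromosome names are kept
    (the exchanged content moves between the existing names)."""
    pieces: dict[str, list[_Piece]] = {
        chrom: [_Piece(chrom, 0, len(seq), "+")] for chrom, seq in assembly.items()
    }
    lengths = {c: sum(p.length for p in ps) for c, ps in pieces.items()}

    for ev in spec.events:
        if isinstance(ev, Inversion):
            if ev.chrom not in pieces:
                raise KeyError(f"unknown chromosome {ev.chrom!r}")
            n = lengths[ev.chrom]
            if not (0 <= ev.start < ev.end <= n):
                raise ValueError(f"inversion [{ev.start},{ev.end}) outside [0,{n})")
            left, rest = _split_pieces(pieces[ev.chrom], ev.start)
            mid, right = _split_pieces(rest, ev.end - ev.start)
            pieces[ev.chrom] = left + _flip(mid) + right
        elif isinstance(ev, ReciprocalTranslocation):
            if ev.chrom_a == ev.chrom_b:
                raise ValueError("reciprocal translocation needs two distinct chromosomes")
            for chrom, bp in ((ev.chrom_a, ev.breakpoint_a), (ev.chrom_b, ev.breakpoint_b)):
                if chrom not in pieces:
                    raise KeyError(f"unknown chromosome {chrom!r}")
                if not (0 <= bp <= lengths[chrom]):
                    raise ValueError(f"breakpoint {bp} outside [0,{lengths[chrom]}]")
            head_a, tail_a = _split_pieces(pieces[ev.chrom_a], ev.breakpoint_a)
            head_b, tail_b = _split_pieces(pieces[ev.chrom_b], ev.breakpoint_b)
            pieces[ev.chrom_a] = head_a + tail_b
            pieces[ev.chrom_b] = head_b + tail_a
            lengths[ev.chrom_a] = sum(p.length for p in pieces[ev.chrom_a])
            lengths[ev.chrom_b] = sum(p.length for p in pieces[ev.chrom_b])
        else:  # pragma: no cover
            raise TypeError(f"unknown event type {type(ev).__name__}")

    out: dict[str, str] = {}
    for chrom, ps in pieces.items():
        parts = []
        for p in ps:
            s = assembly[p.src_chrom][p.src_start : p.src_end]
            parts.append(s if p.strand == "+" else revcomp(s))
        out[chrom] = "".join(parts)
    return out, CoordinateMap(pieces)


# ---------------------------------------------------------------------------
# trios


@dataclass(frozen=True)
class RecombinationSpec:
    """Crossover placement for gametes: either explicit positions per
    chromosome, or a Poisson-mean count with uniform positions."""

    crossovers: Mapping[str, Sequence[int]] | None = None
    mean_per_chrom: float = 1.0


@dataclass(frozen=True)
class PhaseBlock:
    chrom: str
    start: int
    end: int
    parent: str  # 'p1' or 'p2'
    hap: int  # parental haplotype index 0/1


Diploid = Mapping[str, tuple[str, str]]


def _gamete(
    parent: Diploid,
    parent_label: str,
    recomb: RecombinationSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[PhaseBlock]]:
    gamete: dict[str, str] = {}
    blocks: list[PhaseBlock] = []
    for chrom in sorted(parent):
        h0, h1 = parent[chrom]
        if len(h0) != len(h1):
            raise ValueError(f"parent haplotypes of {chrom} differ in length")
        n = len(h0)
        if recomb.crossovers is not None:
            xs = sorted(recomb.crossovers.get(chrom, ()))
        else:
            k = rng.poisson(recomb.mean_per_chrom)
            xs = sorted(int(x) for x in rng.integers(1, n, size=k)) if k else []
        cur = int(rng.integers(0, 2))
        bounds = [0] + [x for x in xs if 0 < x < n] + [n]
        parts = []
        for s, e in zip(bounds, bounds[1:]):
            if e <= s:
                continue
            parts.append((h0 if cur == 0 else h1)[s:e])
            blocks.append(PhaseBlock(chrom, s, e, parent_label, cur))
            cur = 1 - cur
        gamete[chrom] = "".join(parts)
    return gamete, blocks


def simulate_trio(
    parent1: Diploid,
    parent2: Diploid,
    recomb: RecombinationSpec | None = None,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, str]], list[PhaseBlock]]:
    """Draw a diploid child: haplotype 1 is a parent-1 gamete, haplotype 2 a
    parent-2 gamete; the phase truth records the parental haplotype of every
    base. Deterministic given seed."""
    if set(parent1) != set(parent2):
        raise ValueError("parents have mismatched chromosome sets")
    recomb = recomb or RecombinationSpec()
    g1, b1 = _gamete(parent1, "p1", recomb, _rng(seed, "trio", 1))
    g2, b2 = _gamete(parent2, "p2", recomb, _rng(seed, "trio", 2))
    child = {chrom: (g1[chrom], g2[chrom]) for chrom in g1}
    return child, b1 + b2


# ---------------------------------------------------------------------------
# codon-alignment pairs for the Ks clock


_SENSE_CODONS = sorted(c for c, aa in molevo.STANDARD_CODE.items() if aa != "*")


def _syn_neighbours(codon: str) -> list[tuple[int, str]]:
    aa = molevo.STANDARD_CODE[codon]
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if molevo.STANDARD_CODE[nb] == aa:
                out.append((pos, b))
    return out


def _evolve_synonymous(
    codons: list[str], t_years: float, rate: float, rng: np.random.Generator
) -> list[str]:
    """Place synonymous substitution events along one lineage.

    Events arrive as a Poisson process with expectation rate * t * S over the
    gene (S = NG86 synonymous sites); each event picks a codon position with
    probability proportional to its fractional synonymous site count and a
    target uniformly among the synonymous neighbours, so multiple hits and
    back-substitutions occur naturally and exercise the downstream
    Jukes--Cantor correction. No stop codon can ever arise (targets are
    synonymous by construction).
    """
    codons = list(codons)
    weights = np.array([molevo.codon_sites(c) for c in codons])
    total = weights.sum()
    n_events = rng.poisson(rate * t_years * total)
    for _ in range(n_events):
        w = weights / weights.sum()
        i = int(rng.choice(len(codons), p=w))
        neigh = _syn_neighbours(codons[i])
        # target uniform among the codon's synonymous single-nt changes
        pos, b = neigh[int(rng.integers(0, len(neigh)))]
        codons[i] = codons[i][:pos] + b + codons[i][pos + 1 :]
        weights[i] = molevo.codon_sites(codons[i])
    return codons


def sample_gene_pairs(
    t_years: float,
    rate: float = molevo.MUSACEAE_SYN_RATE,
    n_genes: int = 500,
    codons_per_gene: int = 300,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Ortholog codon-alignment pairs diverged 2*T*rate at synonymous sites.

    Each gene's ancestral sequence is drawn uniformly over sense codons, and
    the two descendants each evolve independently for ``t_years`` under the
    synonymous-only event process. Gapless; never introduces stop codons.
    """
    if t_years < 0:
        raise ValueError(f"divergence time must be >= 0, got {t_years}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if n_genes < 1 or codons_per_gene < 1:
        raise ValueError("need at least one gene and one codon")
    out: dict[str, tuple[str, str]] = {}
    for g in range(n_genes):
        rng = _rng(seed, "genes", g)
        root = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), codons_per_gene)]
        a = _evolve_synonymous(root, t_years, rate, rng)
        b = _evolve_synonymous(root, t_years, rate, rng)
        out[f"gene{g:05d}"] = ("".join(a), "".join(b))
    return out
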