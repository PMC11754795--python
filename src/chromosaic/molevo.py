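"""Nei--Gojobori (NG86) Ks/Ka estimation and molecular-clock divergence dating.

The NG86 method partitions each codon's three positions into fractional
synonymous (S) and nonsynonymous (N) site counts by enumerating the nine
single-nucleotide neighbours, and classifies observed between-sequence codon
differences (Sd, Nd) the same way, averaging over all orderings of single
steps when codons differ at more than one position. Proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes--Cantor formula

    d = -(3/4) * ln(1 - 4p/3),

undefined (saturated) for p >= 3/4.

Divergence times follow the molecular-clock relation

    T = median(Ks) / (2 * rate)

with the Musaceae synonymous substitution rate 4.5e-9 per site per year as
the default clock calibration.

Conventions (documented because NG86 implementations differ):

- mutational neighbours that are stop codons are excluded from site counting,
  with the per-position denominator reduced accordingly;
- substitution pathways passing through a stop codon are excluded from
  difference counting; the vanishingly rare codon pairs whose every pathway
  is blocked are dropped entirely (neither sites nor differences counted);
- codons containing a gap, an ambiguity code or a stop in either sequence are
  dropped pairwise;
- the genetic code defaults to the standard nuclear code and is injectable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

MUSACEAE_SYN_RATE = 4.5e-9  # synonymous substitutions / site / year

_BASES = "ACGT"


def _standard_code() -> dict[str, str]:
    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


STANDARD_CODE: dict[str, str] = _standard_code()


@dataclass(frozen=True)
class KsEstimate:
    """NG86 site and difference counts with Jukes--Cantor-corrected rates.

    ``ds``/``dn`` are ``nan`` when the corresponding proportion is saturated
    (p >= 3/4) or when the site count is zero.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    codons_used: int
    codons_skipped: int
    saturated_s: bool
    saturated_n: bool


@dataclass(frozen=True)
class DivergenceEstimate:
    """A dated assembly pair: T = median_ks / (2 * rate), in years."""

    pair: tuple[str, str]
    median_ks: float
    rate: float
    t_years: float


def jc_correct(p: float) -> float:
    """Jukes--Cantor multiple-hit correction; nan at or beyond saturation."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _check_codon(codon: str, code: Mapping[str, str]) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    if code[codon] == "*":
        raise ValueError(f"stop codon has no NG86 site decomposition: {codon!r}")


@lru_cache(maxsize=None)
def _codon_sites_std(codon: str) -> float:
    return codon_sites(codon, STANDARD_CODE)


def codon_sites(codon: str, code: Mapping[str, str] | None = None) -> float:
    """Fractional count of synonymous sites in one sense codon.

    Per position, the fraction of single-nucleotide changes that are
    synonymous, among changes not producing a stop codon (the denominator is
    reduced when a neighbour is a stop). Summed over the three positions;
    the nonsynonymous complement is ``3 - codon_sites(codon)`` minus the
    stop-reduced mass, handled jointly in :func:`pairwise_ng86`.
    """
    if code is None:
        return _codon_sites_std(codon)
    _check_codon(codon, code)
    aa = code[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if code[neighbour] == "*":
                continue
            denom += 1
            if code[neighbour] == aa:
                syn += 1
        if denom:
            total += syn / denom
    return total


def _codon_diffs(c1: str, c2: str, code: Mapping[str, str]) -> tuple[float, float] | None:
    """Average (Sd, Nd) over all stop-free single-step pathways c1 -> c2.

    Returns ``None`` when every pathway passes through a stop codon.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        current = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code[nxt] == "*":
                blocked = True
                break
            if code[nxt] == code[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:
        return None
    sd_mean = sum(p[0] for p in pathways) / len(pathways)
    nd_mean = sum(p[1] for p in pathways) / len(pathways)
    return sd_mean, nd_mean


def _usable(codon: str, code: Mapping[str, str]) -> bool:
    return (
        len(codon) == 3
        and all(b in _BASES for b in codon)
        and code[codon] != "*"
    )


def pairwise_ng86(
    seq1: str, seq2: str, code: Mapping[str, str] | None = None
) -> KsEstimate:
    """NG86 estimate for one pair of aligned, gapless-by-codon sequences.

    Codons containing gaps, ambiguity codes or stops in either sequence are
    skipped in both. Site counts are averaged over the two sequences. The
    result is symmetric in the order of the sequences.
    """
    code = code if code is not None else STANDARD_CODE
    if len(seq1) != len(seq2):
        raise ValueError(f"aligned lengths differ: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3:
        raise ValueError(f"alignment length {len(seq1)} not a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()

    s_sites = n_sites = sd = nd = 0.0
    used = skipped = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (_usable(c1, code) and _usable(c2, code)):
            skipped += 1
            continue
        diffs = _codon_diffs(c1, c2, code)
        if diffs is None:
            skipped += 1
            continue
        s1 = codon_sites(c1, None if code is STANDARD_CODE else code)
        s2 = codon_sites(c2, None if code is STANDARD_CODE else code)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        sd += diffs[0]
        nd += diffs[1]
        used += 1

    ps = sd / s_sites if s_sites > 0 else math.nan
    pn = nd / n_sites if n_sites > 0 else math.nan
    saturated_s = bool(ps >= 0.75) if not math.isnan(ps) else True
    saturated_n = bool(pn >= 0.75) if not math.isnan(pn) else True
    ds = jc_correct(ps) if not math.isnan(ps) else math.nan
    dn = jc_correct(pn) if not math.isnan(pn) else math.nan
    return KsEstimate(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        codons_used=used,
        codons_skipped=skipped,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
    )


def median_ks(
    alignments: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    code: Mapping[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Median Ks over a set of ortholog codon alignments for one pair.

    The median is taken over genes with a defined (non-saturated) dS;
    saturated and skipped genes are counted in the returned per-gene table.
    Even-count medians use the mean of the central pair.
    """
    if not isinstance(alignments, Mapping):
        alignments = {f"gene{i:05d}": pair for i, pair in enumerate(alignments)}
    rows = []
    for gene, (a, b) in alignments.items():
        est = pairwise_ng86(a, b, code)
        rows.append(
            {
                "gene": gene,
                "S": est.s_sites,
                "N": est.n_sites,
                "Sd": est.sd,
                "Nd": est.nd,
                "Ks": est.ds,
                "Ka": est.dn,
                "saturated": est.saturated_s,
                "codons_used": est.codons_used,
            }
        )
    table = pd.DataFrame(rows)
    usable = table.loc[~table["saturated"], "Ks"].dropna()
    if usable.empty:
        raise ValueError("no gene with a defined, non-saturated Ks")
    return float(usable.median()), table


def divergence_time(median_ks_value: float, rate: float = MUSACEAE_SYN_RATE) -> float:
    """Clock dating: T (years) = median Ks / (2 * rate)."""
    if rate <= 0:
        raise ValueError(f"substitution rate must be positive, got {rate}")
    if median_ks_value < 0:
        raise ValueError(f"median Ks must be >= 0, got {median_ks_value}")
    return median_ks_value / (2.0 * rate)


def date_pair(
    name_a: str,
    name_b: str,
    alignments: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    rate: float = MUSACEAE_SYN_RATE,
) -> tuple[DivergenceEstimate, pd.DataFrame]:
    """Median-Ks divergence date for one assembly pair, with per-gene table."""
    med, table = median_ks(alignments)
    est = DivergenceEstimate(
        pair=(name_a, name_b), median_ks=med, rate=rate, t_years=divergence_time(med, rate)
    )
    return est, table
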