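"""Independent brute-force oracles used only by the test suite.

Each oracle is written from first principles, sharing no code with the
package (including its own literal genetic-code table), so agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from itertools import permutations

# standard nuclear genetic code, written out literally
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def ng86_sites(codon: str) -> float:
    """Fractional synonymous sites by explicit neighbour enumeration."""
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = denom = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[neighbour] == "*":
                continue
            denom += 1
            if GENETIC_CODE[neighbour] == aa:
                syn += 1
        if denom:
            total += syn / denom
    return total


def ng86_pair(seq1: str, seq2: str):
    """Brute-force NG86: returns (S, N, Sd, Nd, pS, pN, dS, dN)."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            continue
        diff_positions = [p for p in range(3) if c1[p] != c2[p]]
        paths = []
        for order in permutations(diff_positions):
            cur, sd, nd, ok = c1, 0, 0, True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if GENETIC_CODE[nxt] == "*":
                    ok = False
                    break
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if diff_positions and not paths:
            continue  # every pathway stop-blocked: codon dropped
        S += (ng86_sites(c1) + ng86_sites(c2)) / 2
        N += 3 - (ng86_sites(c1) + ng86_sites(c2)) / 2
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
    pS = Sd / S if S else math.nan
    pN = Nd / N if N else math.nan
    dS = -0.75 * math.log(1 - 4 * pS / 3) if pS < 0.75 else math.nan
    dN = -0.75 * math.log(1 - 4 * pN / 3) if pN < 0.75 else math.nan
    return S, N, Sd, Nd, pS, pN, dS, dN


def revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def naive_kmer_scan(assembly: dict[str, str], kmers: set[str], k: int):
    """Sliding-window exact scan on both strands; hits keyed by canonical
    spelling of the window."""
    hits = []
    for chrom, seq in assembly.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            win = seq[i : i + k]
            if "N" in win:
                continue
            if win in kmers:
                hits.append((chrom, i, "+", win))
            elif revcomp(win) in kmers:
                hits.append((chrom, i, "-", revcomp(win)))
    return sorted(hits)


def diagnostic_kmers(panels: dict[str, list[str]], k: int, min_freq: float = 1.0):
    """Set-difference tag discovery on canonical k-mers."""

    def canon(s):
        r = revcomp(s)
        return s if s <= r else r

    def kmers(seq):
        return {
            canon(seq[i : i + k])
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        }

    per_group = {g: [kmers(s.upper()) for s in seqs] for g, seqs in panels.items()}
    union = {g: set().union(*ks) for g, ks in per_group.items()}
    out = {}
    for g, ks in per_group.items():
        other = set().union(*(u for h, u in union.items() if h != g))
        out[g] = {
            kmer
            for kmer in union[g] - other
            if sum(kmer in s for s in ks) / len(ks) >= min_freq
        }
    return out


def longest_chain_exhaustive(pairs, max_gap):
    """Longest collinear chain by depth-first enumeration (small n only)."""
    pairs = sorted(pairs)
    n = len(pairs)
    best = []

    def extend(chain, orient):
        nonlocal best
        if len(chain) > len(best):
            best = list(chain)
        last = chain[-1]
        for p in pairs:
            da = p[0] - last[0]
            db = p[1] - last[1] if orient == "+" else last[1] - p[1]
            if da > 0 and db > 0 and da + db <= max_gap:
                chain.append(p)
                extend(chain, orient)
                chain.pop()

    for start in pairs:
        for orient in "+-":
            extend([start], orient)
    return best


def greedy_chain_partition(pairs, max_gap, min_block):
    """Best-first extraction of exhaustive longest chains: the oracle for
    chain_blocks' gene counts on small instances."""
    remaining = list(pairs)
    sizes = []
    while remaining:
        chain = longest_chain_exhaustive(remaining, max_gap)
        if len(chain) < min_block:
            break
        sizes.append(len(chain))
        used = set(chain)
        remaining = [p for p in remaining if p not in used]
    return sorted(sizes, reverse=True)


def count_split_support(global_newick: str, gene_newicks: list[str]):
    """Exhaustive bipartition counting through dendropy's own bipartition
    machinery (independent of the package's split extraction)."""
    import dendropy

    ns = dendropy.TaxonNamespace()
    gtree = dendropy.Tree.get(data=global_newick, schema="newick", taxon_namespace=ns)
    gtree.encode_bipartitions()
    all_taxa = {t.label for t in ns if t.label}

    results = {}
    for edge in gtree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        support = evaluable = 0
        for nwk in gene_newicks:
            ns2 = dendropy.TaxonNamespace()
            gt = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns2)
            gt_taxa = {l.taxon.label for l in gt.leaf_node_iter()}
            a = side & gt_taxa
            b = (all_taxa - side) & gt_taxa
            if not a or not b:
                continue
            evaluable += 1
            if len(a) < 2 or len(b) < 2:
                support += 1
                continue
            found = False
            for e in gt.preorder_edge_iter():
                if e.head_node.parent_node is None:
                    continue
                below = frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                if below == a or below == frozenset(gt_taxa) - a:
                    found = True
                    break
            if found:
                support += 1
        key = frozenset(side if min(all_taxa) not in side else all_taxa - side)
        results[key] = (support, evaluable)
    return results
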