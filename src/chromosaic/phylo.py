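"""Distance trees, bipartitions, and gene-tree branch-support proportions.

The headline statistic here is branch support computed as the proportion of
per-gene phylogenies containing each internal bipartition of a global tree
(unrooted comparison). Gene trees over taxon subsets are handled by
restriction: a bipartition is evaluable in a gene tree iff both sides still
intersect the gene tree's taxa after restriction, and only evaluable trees
enter the denominator. Polytomies support only the bipartitions they
actually induce. Alternative placements of a focal taxon are scored by
matching its sister set in each gene tree against candidate branches.

Tree inference for desk-scale runs is neighbour joining on Jukes--Cantor
distances; the support statistics accept any newick gene trees, including
externally produced maximum-likelihood trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj


def jc_distance(p: float) -> float:
    """Jukes--Cantor distance from a mismatch proportion; nan at p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(
    alignments: Mapping[str, Mapping[str, str]] | Mapping[str, str],
    concatenate: bool = True,
) -> pd.DataFrame:
    """Pairwise JC distances over one alignment or a concatenated gene set.

    ``alignments`` is either ``{taxon: sequence}`` or
    ``{gene: {taxon: sequence}}`` (with ``concatenate=True`` genes are
    concatenated per taxon first; all genes must share the taxon set).
    Saturated pairs (p-distance >= 3/4) are nan-flagged.
    """
    first = next(iter(alignments.values()))
    if isinstance(first, str):
        per_taxon: dict[str, str] = dict(alignments)  # type: ignore[arg-type]
    else:
        if not concatenate:
            raise ValueError("per-gene matrices: call once per gene")
        taxa = set(first)
        per_taxon = {t: "" for t in taxa}
        for gene, aln in alignments.items():  # type: ignore[union-attr]
            if set(aln) != taxa:
                raise ValueError(f"gene {gene!r} has a different taxon set")
            for t in taxa:
                per_taxon[t] += aln[t]
    taxa_list = sorted(per_taxon)
    n = len(taxa_list)
    lengths = {len(s) for s in per_taxon.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = per_taxon[taxa_list[i]], per_taxon[taxa_list[j]]
            p = sum(x != y for x, y in zip(a, b)) / len(a)
            mat[i, j] = mat[j, i] = jc_distance(p)
    return pd.DataFrame(mat, index=taxa_list, columns=taxa_list)


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbour-joining tree (newick) from a symmetric distance matrix.

    On additive matrices NJ recovers the generating topology and branch
    lengths exactly. Saturated (nan) entries are an error.
    """
    mat = distances.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains saturated (nan) entries")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")
    if len(distances) < 3:
        raise ValueError("need at least 3 taxa")
    dm = DistanceMatrix(mat, ids=list(distances.index))
    tree = nj(dm)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# bipartitions and support


def _parse(newick: str, namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=namespace or dendropy.TaxonNamespace()
    )


def tree_splits(
    tree: dendropy.Tree, include_trivial: bool = False
) -> set[frozenset[str]]:
    """Unrooted bipartitions as the leaf-label set of one side.

    Each internal edge contributes the smaller-or-canonical side; we store
    the side NOT containing the alphabetically first taxon so each split has
    one canonical spelling. Trivial splits (singleton either side) are
    excluded unless requested.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor not in below else leaves - below
        if not side or side == leaves:
            continue
        if not include_trivial and (len(side) < 2 or len(leaves - side) < 2):
            continue
        splits.add(side)
    return splits


def _canonical_side(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    anchor = min(leaves)
    return side if anchor not in side else leaves - side


@dataclass(frozen=True)
class BranchSupport:
    split: frozenset[str]  # canonical side (not containing first taxon)
    supporting: int
    evaluable: int

    @property
    def proportion(self) -> float:
        return self.supporting / self.evaluable if self.evaluable else math.nan


def branch_support(
    global_newick: str, gene_newicks: Sequence[str]
) -> list[BranchSupport]:
    """Proportion of gene trees containing each internal bipartition of the
    global tree (unrooted; gene trees may cover taxon subsets).

    For each internal split of the global tree and each gene tree: restrict
    the split to the gene tree's taxa; it is evaluable iff both restricted
    sides are non-empty; it is supported iff the restricted split is trivial
    (present in any tree) or occurs among the gene tree's splits.
    """
    if not gene_newicks:
        raise ValueError("no gene trees")
    gtree = _parse(global_newick)
    global_leaves = frozenset(l.taxon.label for l in gtree.leaf_node_iter())
    targets = tree_splits(gtree)

    gene_info = []
    for nwk in gene_newicks:
        t = _parse(nwk)
        leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
        gene_info.append((leaves, tree_splits(t, include_trivial=True)))

    out = []
    for split in sorted(targets, key=lambda s: (len(s), tuple(sorted(s)))):
        other = global_leaves - split
        supporting = evaluable = 0
        for leaves, gsplits in gene_info:
            side_a = split & leaves
            side_b = other & leaves
            if not side_a or not side_b:
                continue
            evaluable += 1
            if len(side_a) < 2 or len(side_b) < 2:
                supporting += 1  # trivial after restriction: always present
                continue
            if _canonical_side(side_a, leaves) in gsplits:
                supporting += 1
        out.append(BranchSupport(split, supporting, evaluable))
    return out


def support_table(supports: Sequence[BranchSupport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "split": "|".join(sorted(s.split)),
                "supporting": s.supporting,
                "evaluable": s.evaluable,
                "proportion": s.proportion,
            }
            for s in supports
        ]
    )


def annotate_support(global_newick: str, supports: Sequence[BranchSupport]) -> str:
    """Write supports as internal node labels of the global tree."""
    tree = _parse(global_newick)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    by_split = {s.split: s for s in supports}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        s = by_split.get(_canonical_side(below, leaves))
        if s is not None and s.evaluable:
            node.label = f"{s.proportion:.3f}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _sister_set(tree: dendropy.Tree, focal: str) -> frozenset[str]:
    """The focal taxon's smallest non-trivial split side, minus the focal:
    its sister group in the unrooted tree."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    best: frozenset[str] | None = None
    for node in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        for side in (below, leaves - below):
            if focal in side and 1 < len(side) < len(leaves):
                if best is None or len(side) < len(best):
                    best = side
    if best is None:
        raise ValueError(f"cannot locate {focal!r} attachment (tree too small)")
    return best - {focal}


def placement_support(
    global_newick: str,
    focal: str,
    candidate_sisters: Mapping[str, Iterable[str]],
    gene_newicks: Sequence[str],
) -> dict[str, float]:
    """Score alternative attachments of ``focal`` over the gene trees.

    ``candidate_sisters`` names each candidate branch by the taxon set that
    would be the focal taxon's sister if it attached there (a side of a
    branch of the global tree with the focal removed). Per gene tree
    containing the focal taxon, its observed sister set (restricted
    comparison on shared taxa) is matched against the candidates; unmatched
    attachments accrue to "other". Returns proportions over evaluable trees,
    summing to 1 with "other".
    """
    gtree = _parse(global_newick)
    if focal not in {l.taxon.label for l in gtree.leaf_node_iter()}:
        raise ValueError(f"focal taxon {focal!r} not in global tree")
    candidates = {name: frozenset(side) for name, side in candidate_sisters.items()}
    counts = {name: 0 for name in candidates}
    counts["other"] = 0
    evaluable = 0
    for nwk in gene_newicks:
        t = _parse(nwk)
        leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
        if focal not in leaves or len(leaves) < 3:
            continue
        evaluable += 1
        sister = _sister_set(t, focal)
        shared = leaves - {focal}
        matched = None
        for name, side in candidates.items():
            if side & shared == sister:
                matched = name
                break
        counts[matched if matched is not None else "other"] += 1
    if evaluable == 0:
        raise ValueError("no gene tree contains the focal taxon")
    return {name: c / evaluable for name, c in counts.items()}
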