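"""Collinear chaining, block association, ortholog groups, dot plots."""

import numpy as np
import pytest

import oracles
from chromosaic import synteny
from chromosaic.seqio import BedRecord
from chromosaic.synteny import GeneAnchor, chain_blocks


def make_pairs(perm, chrom_a="a1", chrom_b="b1"):
    """Anchor pairs from a permutation: gene i sits at rank i in A and rank
    perm[i] in B."""
    pairs = []
    for i, r in enumerate(perm):
        a = GeneAnchor(f"g{i}", "A", chrom_a, i, i * 1000 + 500)
        b = GeneAnchor(f"g{i}'", "B", chrom_b, r, r * 1000 + 500)
        pairs.append((a, b))
    return pairs


class TestChaining:
    def test_identical_order_single_forward_block(self):
        blocks = chain_blocks(make_pairs(range(30)))
        assert len(blocks) == 1
        assert blocks[0].orientation == "+"
        assert blocks[0].gene_count == 30

    def test_internal_inversion_three_blocks(self):
        """Genes 0-29 with 10-19 reversed in B: blocks +10, -10, +10."""
        perm = list(range(10)) + list(range(19, 9, -1)) + list(range(20, 30))
        blocks = chain_blocks(make_pairs(perm))
        got = sorted((b.orientation, b.gene_count) for b in blocks)
        assert got == [("+", 10), ("+", 10), ("-", 10)]
        # matches the exhaustive best-first chain partition
        simple = [(a.rank, b.rank) for a, b in make_pairs(perm)]
        assert sorted((b.gene_count for b in blocks), reverse=True) == (
            oracles.greedy_chain_partition(simple, max_gap=10, min_block=5)
        )

    def test_no_shared_genes_empty(self):
        assert chain_blocks([]) == []

    def test_duplicate_gene_rejected(self):
        pairs = make_pairs(range(6))
        dup = (pairs[0][0], GeneAnchor("other", "B", "b1", 50, 50_500))
        with pytest.raises(ValueError):
            chain_blocks(pairs + [dup], min_block=1)

    def test_monotonicity_audit_and_oracle_equivalence_random(self):
        """Random shuffled instances: every block passes a monotonicity
        audit and gene counts match the exhaustive chain partition."""
        rng = np.random.default_rng(0)
        for trial in range(8):
            n = int(rng.integers(8, 18))
            perm = rng.permutation(n).tolist()
            pairs = make_pairs(perm)
            blocks = chain_blocks(pairs, max_gap=4, min_block=2)
            for b in blocks:
                a_ranks = [a.rank for a, _ in b.pairs]
                b_ranks = [x.rank for _, x in b.pairs]
                assert a_ranks == sorted(a_ranks)
                expected = sorted(b_ranks) if b.orientation == "+" else sorted(b_ranks, reverse=True)
                assert b_ranks == expected
            simple = [(a.rank, x.rank) for a, x in pairs]
            oracle_sizes = oracles.greedy_chain_partition(simple, max_gap=4, min_block=2)
            assert sorted((b.gene_count for b in blocks), reverse=True) == oracle_sizes

    def test_symmetry_of_anchor_pair_sets(self):
        perm = list(range(10)) + list(range(19, 9, -1)) + list(range(20, 30))
        pairs = make_pairs(perm)
        fwd = chain_blocks(pairs)
        rev = chain_blocks([(b, a) for a, b in pairs])
        fwd_sets = sorted(sorted((a.gene, b.gene) for a, b in blk.pairs) for blk in fwd)
        rev_sets = sorted(sorted((b.gene, a.gene) for a, b in blk.pairs) for blk in rev)
        assert fwd_sets == rev_sets


def ref_block(genes, member_prefix, chrom="r1"):
    """Reference-vs-assembly block over the given reference gene names."""
    pairs = tuple(
        (
            GeneAnchor(g, "ref", chrom, i, i * 1000),
            GeneAnchor(f"{member_prefix}{g}", member_prefix, "c1", i, i * 1000),
        )
        for i, g in enumerate(genes)
    )
    return synteny.SyntenyBlock("ref", member_prefix, chrom, "c1", pairs, "+")


class TestAssociation:
    def test_strictly_more_than_20_shared_genes(self):
        genes = [f"g{i}" for i in range(40)]
        bx = ref_block(genes[:21], "x")
        by21 = ref_block(genes[:21], "y")  # 21 shared
        by20 = ref_block(genes[:20], "y")  # exactly 20 shared
        assert synteny.associate_blocks([bx], [by21]) == [(bx, by21, 21)]
        assert synteny.associate_blocks([bx], [by20]) == []

    def test_zero_shared_not_associated(self):
        bx = ref_block([f"g{i}" for i in range(25)], "x")
        by = ref_block([f"h{i}" for i in range(25)], "y")
        assert synteny.associate_blocks([bx], [by]) == []


class TestOrthologGroups:
    def test_identical_assemblies_full_groups(self):
        genes = [f"g{i}" for i in range(30)]
        blocks = {"X": [ref_block(genes, "x")], "Y": [ref_block(genes, "y")]}
        groups = synteny.build_ortholog_groups(blocks)
        assert len(groups) == 30
        g0 = next(g for g in groups if g.ref_gene == "g0")
        assert g0.members == {"X": "xg0", "Y": "yg0"}

    def test_group_count_matches_bruteforce_on_inverted_layout(self):
        """Three assemblies, one with a small displaced block: group count
        equals a brute-force intersection over mutually associated blocks."""
        genes = [f"g{i}" for i in range(60)]
        bx = ref_block(genes, "x")
        by1 = ref_block(genes[:25], "y")
        by2 = ref_block(genes[40:], "y")  # 20 genes: never associated
        blocks = {"X": [bx], "Y": [by1, by2]}
        groups = synteny.build_ortholog_groups(blocks)
        # brute force: a gene forms a group iff every pair of blocks holding
        # it shares > 20 reference genes
        expected = 0
        for g in genes:
            holders = []
            for blist in blocks.values():
                for b in blist:
                    if g in b.a_genes:
                        holders.append(b)
            if all(
                len(h1.a_genes & h2.a_genes) > 20
                for i, h1 in enumerate(holders)
                for h2 in holders[i + 1 :]
            ):
                expected += 1
        assert len(groups) == expected
        # the 20-gene tail block fails association with bx, so those genes
        # appear only as X singletons
        tail = [g for g in groups if g.ref_gene in genes[40:]]
        assert all(set(g.members) == {"X"} for g in tail)

    def test_complete_occupancy_flag(self):
        genes = [f"g{i}" for i in range(30)]
        blocks = {"X": [ref_block(genes, "x")], "Y": [ref_block(genes[:25], "y")]}
        full = synteny.build_ortholog_groups(blocks, complete_occupancy=True)
        assert len(full) == 25
        assert all(set(g.members) == {"X", "Y"} for g in full)

    def test_empty_when_no_associated_blocks_and_occupancy_required(self):
        genes = [f"g{i}" for i in range(30)]
        blocks = {"X": [ref_block(genes, "x")], "Y": []}
        assert synteny.build_ortholog_groups(blocks, complete_occupancy=True) == []

    def test_conflicting_members_drop_group(self, caplog):
        genes = [f"g{i}" for i in range(25)]
        b1 = ref_block(genes, "x")
        # second block maps g0 to a different X gene
        pairs = tuple(
            (GeneAnchor(g, "ref", "r2", i, i * 1000), GeneAnchor(f"alt_{g}", "x", "c2", i, i * 1000))
            for i, g in enumerate(genes)
        )
        b2 = synteny.SyntenyBlock("ref", "x", "r2", "c2", pairs, "+")
        with caplog.at_level("WARNING"):
            groups = synteny.build_ortholog_groups({"X": [b1, b2]})
        assert groups == []
        assert "conflicting" in caplog.text


class TestAncestryFilter:
    ANCHORS = {
        "m1": GeneAnchor("m1", "focal", "c1", 0, 5_000),
        "m2": GeneAnchor("m2", "focal", "c1", 1, 15_000),
    }
    GROUPS = [
        synteny.OrthologGroup("g1", {"focal": "m1"}),
        synteny.OrthologGroup("g2", {"focal": "m2"}),
    ]

    def test_interval_membership(self):
        segs = [BedRecord("c1", 0, 10_000, "U"), BedRecord("c1", 10_000, 20_000, "A")]
        kept = synteny.filter_groups_by_ancestry(self.GROUPS, self.ANCHORS, segs, "U", "focal")
        assert [g.ref_gene for g in kept] == ["g1"]

    def test_no_target_segments_empty(self):
        segs = [BedRecord("c1", 0, 20_000, "A")]
        assert synteny.filter_groups_by_ancestry(self.GROUPS, self.ANCHORS, segs, "U", "focal") == []

    def test_matches_bruteforce_interval_scan(self):
        rng = np.random.default_rng(4)
        bounds = sorted(rng.choice(range(1000, 99_000), size=9, replace=False).tolist())
        edges = [0] + bounds + [100_000]
        labels = [("U" if i % 2 else "A") for i in range(len(edges) - 1)]
        segs = [BedRecord("c1", s, e, l) for s, e, l in zip(edges, edges[1:], labels)]
        anchors = {}
        groups = []
        mids = rng.integers(0, 100_000, size=50)
        for i, mid in enumerate(mids):
            name = f"m{i}"
            anchors[name] = GeneAnchor(name, "focal", "c1", i, int(mid))
            groups.append(synteny.OrthologGroup(f"g{i}", {"focal": name}))
        kept = synteny.filter_groups_by_ancestry(groups, anchors, segs, "U", "focal")
        expected = {
            f"g{i}"
            for i, mid in enumerate(mids)
            if any(s.start <= mid < s.end and s.label == "U" for s in segs)
        }
        assert {g.ref_gene for g in kept} == expected


class TestDotplot:
    def test_point_count_and_diagonal(self):
        pairs = make_pairs(range(20))
        df = synteny.dotplot_data(pairs)
        assert len(df) == 20
        assert (df.ref_pos == df.target_pos).all()

    def test_inversion_antidiagonal_run(self):
        perm = list(range(5)) + list(range(14, 4, -1)) + list(range(15, 20))
        df = synteny.dotplot_data(make_pairs(perm))
        mid = df.iloc[5:15]
        assert (np.diff(mid.target_pos) < 0).all()
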