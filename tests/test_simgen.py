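"""Synthetic-data generators: clock behaviour, truth tiling, coordinate maps."""

import math

import numpy as np
import pytest

from chromosaic import molevo, simgen
from chromosaic.seqio import revcomp


def jc_expected_p(d: float) -> float:
    """Expected raw mismatch proportion for d substitutions/site under JC."""
    return 0.75 * (1 - math.exp(-4 * d / 3))


class TestAncestralGroups:
    def test_zero_branch_lengths_give_identical_groups(self):
        spec = simgen.GroupPhylogenySpec(
            "((A:0,B:0):0,C:0);", length=3000, within_group_years=0, seed=1
        )
        panels, _ = simgen.simulate_ancestral_groups(spec)
        seqs = {s for panel in panels.values() for s in panel}
        assert len(seqs) == 1

    def test_pairwise_divergence_matches_clock_closed_form(self):
        """Two groups split T=7.8e6 yr at 4.5e-9/yr: the JC-corrected
        observed distance is 2*T*rate within 3 binomial SD."""
        t, rate, length = 7.8e6, 4.5e-9, 300_000
        spec = simgen.GroupPhylogenySpec(
            f"(A:{t:.0f},B:{t:.0f});",
            length=length,
            rate=rate,
            n_seqs_per_group=1,
            within_group_years=0,
            seed=2,
        )
        panels, _ = simgen.simulate_ancestral_groups(spec)
        a, b = panels["A"][0], panels["B"][0]
        p_obs = sum(x != y for x, y in zip(a, b)) / length
        d_true = 2 * t * rate
        p_exp = jc_expected_p(d_true)
        sd = math.sqrt(p_exp * (1 - p_exp) / length)
        assert abs(p_obs - p_exp) < 3 * sd
        d_obs = -0.75 * math.log(1 - 4 * p_obs / 3)
        assert d_obs == pytest.approx(d_true, rel=0.03)

    def test_seed_determinism(self):
        spec = simgen.GroupPhylogenySpec("(A:1e6,B:1e6);", length=5000, seed=7)
        p1, _ = simgen.simulate_ancestral_groups(spec)
        p2, _ = simgen.simulate_ancestral_groups(spec)
        assert p1 == p2

    def test_clock_consistency_regression_slope(self):
        """JC-corrected divergence regressed on 2*T*rate over 5 depths has
        slope 1 +/- 0.05."""
        rate, length = 4.5e-9, 120_000
        depths = [1e6, 2.5e6, 5e6, 7.5e6, 10e6]
        xs, ys = [], []
        for i, t in enumerate(depths):
            spec = simgen.GroupPhylogenySpec(
                f"(A:{t:.0f},B:{t:.0f});",
                length=length,
                rate=rate,
                n_seqs_per_group=1,
                within_group_years=0,
                seed=100 + i,
            )
            panels, _ = simgen.simulate_ancestral_groups(spec)
            p = sum(x != y for x, y in zip(panels["A"][0], panels["B"][0])) / length
            xs.append(2 * t * rate)
            ys.append(-0.75 * math.log(1 - 4 * p / 3))
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            simgen.GroupPhylogenySpec("(A:1);", length=100)  # single group
        with pytest.raises(ValueError):
            simgen.GroupPhylogenySpec("(A:1,B:1);", length=0)
        with pytest.raises(ValueError):
            simgen.GroupPhylogenySpec("(A:1,B:1);", length=100, rate=0)
        with pytest.raises(ValueError):
            simgen.GroupPhylogenySpec("(A:1,B:1);", length=100, codon_structured=True)


class TestMosaic:
    def test_single_donor_covers_whole_chromosome(self, panels):
        spec = simgen.MosaicSpec("chr1", [(200_000, "A", 0)])
        mosaic, truth = simgen.build_mosaic_genome(panels, spec)
        assert mosaic["chr1"] == panels["A"][0]
        assert [(s.start, s.end, s.label) for s in truth.segments] == [(0, 200_000, "A")]

    def test_three_segment_truth_bed(self, panels):
        spec = simgen.MosaicSpec("chrM", [(10_000, "A", 0), (5_000, "B", 0), (10_000, "A", 0)])
        mosaic, truth = simgen.build_mosaic_genome(panels, spec)
        assert [(s.start, s.end, s.label) for s in truth.segments] == [
            (0, 10_000, "A"),
            (10_000, 15_000, "B"),
            (15_000, 25_000, "A"),
        ]
        assert len(mosaic["chrM"]) == 25_000

    def test_truth_tiles_chromosome(self, default_mosaic):
        mosaic, truth = default_mosaic
        assert sum(s.length for s in truth.segments) == len(mosaic["chrM"])
        starts = [s.start for s in truth.segments]
        ends = [s.end for s in truth.segments]
        assert starts[1:] == ends[:-1]

    def test_unknown_donor_and_overrun_errors(self, panels):
        with pytest.raises(KeyError):
            simgen.build_mosaic_genome(panels, simgen.MosaicSpec("c", [(100, "Z", 0)]))
        with pytest.raises(ValueError):
            simgen.build_mosaic_genome(panels, simgen.MosaicSpec("c", [(10**7, "A", 0)]))


class TestRearrangement:
    def test_empty_event_list_is_identity(self):
        asm = {"c": "ACGTACGTAC"}
        out, cmap = simgen.apply_rearrangement(asm, simgen.RearrangementSpec([]))
        assert out == asm
        assert cmap.forward("c", 3) == ("c", 3, "+")

    def test_inversion_reverse_complements_interval(self):
        seq = "A" * 10 + "CCCCCTTTTT" + "G" * 10
        out, cmap = simgen.apply_rearrangement(
            {"c": seq}, simgen.RearrangementSpec([simgen.Inversion("c", 10, 20)])
        )
        assert out["c"] == "A" * 10 + revcomp("CCCCCTTTTT") + "G" * 10
        assert len(out["c"]) == 30
        assert cmap.forward("c", 10) == ("c", 19, "-")

    def test_reciprocal_translocation_exchanges_distal_parts(self):
        asm = {"c1": "AAAATTTT", "c2": "GGGGCCCC"}
        ev = simgen.ReciprocalTranslocation("c1", 4, "c2", 4)
        out, _ = simgen.apply_rearrangement(asm, simgen.RearrangementSpec([ev]))
        assert out["c1"] == "AAAACCCC"
        assert out["c2"] == "GGGGTTTT"

    def test_fig4c_style_recipe_conserves_bases_and_round_trips(self):
        """Inversion on chr7, reciprocal translocation chr1/chr7, inversion on
        the new chr1: length conserved, coordinate map a bijection."""
        rng = np.random.default_rng(3)
        asm = {
            "chr1": simgen.random_sequence(100_000, rng),
            "chr7": simgen.random_sequence(100_000, rng),
        }
        spec = simgen.RearrangementSpec(
            [
                simgen.Inversion("chr7", 20_000, 60_000),
                simgen.ReciprocalTranslocation("chr1", 50_000, "chr7", 40_000),
                simgen.Inversion("chr1", 60_000, 90_000),
            ]
        )
        out, cmap = simgen.apply_rearrangement(asm, spec)
        assert sum(map(len, out.values())) == 200_000
        # base multiset conserved up to complementation
        for chrom in asm:
            for pos in rng.integers(0, 100_000, size=500):
                dst_chrom, dst_pos, strand = cmap.forward(chrom, int(pos))
                src = asm[chrom][pos]
                dst = out[dst_chrom][dst_pos]
                assert dst == (src if strand == "+" else revcomp(src))
                back = cmap.inverse(dst_chrom, dst_pos)
                assert back == (chrom, int(pos), strand)

    def test_breakpoint_validation(self):
        asm = {"c": "ACGT" * 10}
        with pytest.raises(ValueError):
            simgen.apply_rearrangement(
                asm, simgen.RearrangementSpec([simgen.Inversion("c", 10, 100)])
            )
        with pytest.raises(KeyError):
            simgen.apply_rearrangement(
                asm, simgen.RearrangementSpec([simgen.Inversion("zz", 0, 4)])
            )


class TestTrio:
    @pytest.fixture()
    def parents(self):
        rng = np.random.default_rng(8)
        mk = lambda: {"chr1": (simgen.random_sequence(100_000, rng), simgen.random_sequence(100_000, rng))}
        return mk(), mk()

    def test_zero_recombination_child_is_a_parental_gamete(self, parents):
        p1, p2 = parents
        child, truth = simgen.simulate_trio(
            p1, p2, simgen.RecombinationSpec(crossovers={}), seed=4
        )
        h1, h2 = child["chr1"]
        assert h1 in p1["chr1"]
        assert h2 in p2["chr1"]

    def test_single_crossover_gives_two_phase_blocks(self, parents):
        p1, p2 = parents
        child, truth = simgen.simulate_trio(
            p1, p2, simgen.RecombinationSpec(crossovers={"chr1": [50_000]}), seed=4
        )
        for parent in ("p1", "p2"):
            blocks = [b for b in truth if b.parent == parent]
            assert len(blocks) == 2
            assert {(b.start, b.end) for b in blocks} == {(0, 50_000), (50_000, 100_000)}
        # sequence actually recombines as the truth says
        h1 = child["chr1"][0]
        b0, b1 = sorted((b for b in truth if b.parent == "p1"), key=lambda b: b.start)
        assert h1[:50_000] == p1["chr1"][b0.hap][:50_000]
        assert h1[50_000:] == p1["chr1"][b1.hap][50_000:]

    def test_determinism_and_chromosome_set_check(self, parents):
        p1, p2 = parents
        c1, _ = simgen.simulate_trio(p1, p2, seed=9)
        c2, _ = simgen.simulate_trio(p1, p2, seed=9)
        assert c1 == c2
        with pytest.raises(ValueError):
            simgen.simulate_trio(p1, {"chrX": p2["chr1"]}, seed=9)


class TestGenePairs:
    def test_zero_time_identical_pairs(self):
        aln = simgen.sample_gene_pairs(0.0, n_genes=5, codons_per_gene=30, seed=1)
        assert all(a == b for a, b in aln.values())

    def test_no_stop_codons_and_determinism(self):
        aln = simgen.sample_gene_pairs(2e7, n_genes=10, codons_per_gene=50, seed=6)
        for a, b in aln.values():
            for seq in (a, b):
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert codons.isdisjoint({"TAA", "TAG", "TGA"})
        assert aln == simgen.sample_gene_pairs(2e7, n_genes=10, codons_per_gene=50, seed=6)

    def test_median_ks_matches_clock_expectation(self):
        """500 genes x 300 codons at T=7.8e6: median NG86 Ks ~ 2*T*rate."""
        aln = simgen.sample_gene_pairs(7.8e6, 4.5e-9, 500, 300, seed=3)
        med, _ = molevo.median_ks(aln)
        assert med == pytest.approx(2 * 7.8e6 * 4.5e-9, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simgen.sample_gene_pairs(-1.0)
        with pytest.raises(ValueError):
            simgen.sample_gene_pairs(1e6, n_genes=0)
        with pytest.raises(ValueError):
            simgen.sample_gene_pairs(1e6, rate=0)
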