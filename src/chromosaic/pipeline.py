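"""End-to-end demo pipeline on synthetic data, and its JSON configuration.

One call (or ``chromosaic demo``) runs the whole analysis the package
implements, on generated data with known truth: simulate diverged ancestral
panels -> discover diagnostic tags -> build a mosaic hybrid chromosome ->
paint it and score against truth -> simulate a trio, phase markers, parse
contigs into haplotypes -> chain synteny blocks across a rearranged
assembly -> sample ortholog codon alignments -> NG86 median Ks -> clock
dating -> gene trees and branch support. All artefacts (FASTA, BED, TSV,
JSON, newick) are written to an output directory, deterministically for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import haplotypes, molevo, painting, phylo, simgen, synteny, tags
from .seqio import write_bed, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete, JSON-round-trippable configuration of the demo pipeline.

    Defaults are chosen so that an empty config runs a realistic desk-scale
    study: three ancestral groups diverged 7.8/4.4 My under the Musaceae
    synonymous clock, 200-kb chromosomes, k=31 tags, 10-kb painting windows,
    and 300 gene pairs of 200 codons for the Ks dating stage.
    """

    seed: int = 0
    # ancestral panel phylogeny: branch lengths in years
    newick: str = "((A:4400000,B:4400000):3400000,C:7800000);"
    # four-taxon tree for the gene-tree / branch-support stage (an unrooted
    # 3-taxon tree has no internal bipartition to support)
    support_newick: str = "(((A:4400000,B:4400000):3400000,C:7800000):1200000,D:9000000);"
    rate: float = molevo.MUSACEAE_SYN_RATE
    chrom_length: int = 200_000
    n_seqs_per_group: int = 2
    # mosaic recipe: (length, donor group, donor hap)
    mosaic_segments: list[list[Any]] = field(
        default_factory=lambda: [[80_000, "A", 0], [60_000, "B", 0], [60_000, "A", 0]]
    )
    k: int = 31
    min_group_freq: float = 1.0
    window: int = 10_000
    min_hits: int = 5
    ratio: float = 0.75
    # Ks/dating stage
    t_years: float = 7.8e6
    n_genes: int = 300
    codons_per_gene: int = 200
    # trio stage
    trio_markers_every: int = 1  # genotype every site; het sites become markers
    contig_length: int = 20_000
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        simgen.GroupPhylogenySpec(self.newick, self.chrom_length, self.rate, seed=self.seed)
        tags.TagConfig(self.k, self.min_group_freq)
        painting.PaintingConfig(self.window, self.min_hits, self.ratio)
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes and codons_per_gene must be >= 1")


def run_demo_pipeline(config: RunConfig | None = None, outdir: str | Path = "chromosaic_demo") -> dict:
    """Run the full synthetic study; return a report dict (also written as
    JSON) with per-stage runtimes, record counts and headline numbers."""
    cfg = config or RunConfig()
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": dataclasses.asdict(cfg), "stages": {}}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**info):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return done

    # 1. ancestral panels
    done = stage("simulate_panels")
    spec = simgen.GroupPhylogenySpec(
        cfg.newick, cfg.chrom_length, cfg.rate, cfg.n_seqs_per_group, seed=cfg.seed
    )
    panels, tree = simgen.simulate_ancestral_groups(spec)
    for group, seqs in panels.items():
        write_fasta({f"{group}_{i}": s for i, s in enumerate(seqs)}, out / f"panel_{group}.fasta")
    done(groups=len(panels), panel_seqs=sum(map(len, panels.values())))

    # 2. diagnostic tags
    done = stage("discover_tags")
    tag_cfg = tags.TagConfig(cfg.k, cfg.min_group_freq)
    tag_set = tags.discover_tags(panels, tag_cfg)
    tags.write_tags_tsv(tag_set, out / "tags.tsv")
    done(tags=len(tag_set))

    # 3. mosaic + painting
    done = stage("paint_mosaic")
    mosaic_spec = simgen.MosaicSpec(
        "chrM", [(int(l), g, int(h)) for l, g, h in cfg.mosaic_segments], seed=cfg.seed
    )
    mosaic, truth = simgen.build_mosaic_genome(panels, mosaic_spec)
    write_fasta(mosaic, out / "mosaic.fasta")
    write_bed(truth.segments, out / "mosaic_truth.bed")
    paint_cfg = painting.PaintingConfig(cfg.window, cfg.min_hits, cfg.ratio)
    paint = painting.paint_assembly(mosaic, tag_set, paint_cfg, tag_cfg)
    write_bed(paint.to_bed(), out / "mosaic_painting.bed")
    paint.window_table().to_csv(out / "mosaic_windows.tsv", sep="\t", index=False)
    accuracy = painting.accuracy_vs_truth(paint, truth.segments)
    (out / "fractions.json").write_text(json.dumps(paint.fractions, indent=2))
    done(segments=len(paint.segments), accuracy=round(accuracy, 4), fractions=paint.fractions)

    # 4. rearrangement + synteny/dotplot
    done = stage("synteny")
    two_chroms = {
        "chr1": panels[spec.groups[0]][0],
        "chr7": panels[spec.groups[0]][1] if cfg.n_seqs_per_group > 1 else panels[spec.groups[-1]][0],
    }
    n = cfg.chrom_length
    rearr = simgen.RearrangementSpec(
        [
            simgen.Inversion("chr7", n // 4, n // 2),
            simgen.ReciprocalTranslocation("chr1", n // 2, "chr7", n // 2),
            simgen.Inversion("chr1", n // 2, 3 * n // 4),
        ]
    )
    rearranged, coord_map = simgen.apply_rearrangement(two_chroms, rearr)
    write_fasta(rearranged, out / "rearranged.fasta")
    coord_map.write_tsv(out / "coordinate_map.tsv")
    gene_spacing = 2_000
    ref_anchors = []
    tgt_anchors = []
    for chrom in sorted(two_chroms):
        mids = range(gene_spacing // 2, len(two_chroms[chrom]), gene_spacing)
        for i, mid in enumerate(mids):
            gene = f"{chrom}_g{i:04d}"
            ref_anchors.append(synteny.GeneAnchor(gene, "ref", chrom, i, mid))
    mapped = []
    for a in ref_anchors:
        dst_chrom, dst_pos, strand = coord_map.forward(a.chrom, a.midpoint)
        mapped.append((a, dst_chrom, dst_pos, strand))
    by_chrom: dict[str, list] = {}
    for a, dc, dp, st in mapped:
        by_chrom.setdefault(dc, []).append((a, dp, st))
    pairs = []
    for dc, items in sorted(by_chrom.items()):
        items.sort(key=lambda x: x[1])
        for rank, (a, dp, st) in enumerate(items):
            tgt = synteny.GeneAnchor(f"t_{a.gene}", "tgt", dc, rank, dp, st)
            tgt_anchors.append(tgt)
            pairs.append((a, tgt))
    blocks = synteny.chain_blocks(pairs, max_gap=10, min_block=5)
    synteny.blocks_table(blocks).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
    synteny.dotplot_data(pairs).to_csv(out / "dotplot.tsv", sep="\t", index=False)
    done(genes=len(pairs), blocks=len(blocks))

    # 5. trio + haplotype parsing
    done = stage("haplotypes")
    g0, g1 = spec.groups[0], spec.groups[1]
    parent1 = {"chr1": (panels[g0][0], panels[g0][1 % len(panels[g0])])}
    parent2 = {"chr1": (panels[g1][0], panels[g1][1 % len(panels[g1])])}
    child, phase_truth = simgen.simulate_trio(parent1, parent2, seed=cfg.seed)
    h1_seq, h2_seq = child["chr1"]
    positions = range(500, len(h1_seq) - 500, cfg.trio_markers_every)
    child_gt, p1_gt, p2_gt = [], [], []
    for pos in positions:
        a, b = h1_seq[pos], h2_seq[pos]
        if a == b:
            continue
        child_gt.append(haplotypes.Genotype("chr1", pos, (a, b)))
        p1_gt.append(haplotypes.Genotype("chr1", pos, (parent1["chr1"][0][pos], parent1["chr1"][1][pos])))
        p2_gt.append(haplotypes.Genotype("chr1", pos, (parent2["chr1"][0][pos], parent2["chr1"][1][pos])))
    phased, bad = haplotypes.phase_markers_from_trio(child_gt, p1_gt, p2_gt)
    h1_tags, h2_tags = haplotypes.build_haplotype_tags(phased, {"chr1": h1_seq}, cfg.k)
    hap_tags = haplotypes.haplotype_tag_objects(h1_tags, h2_tags)
    counts: dict[str, tuple[int, int]] = {}
    step = cfg.contig_length
    for start in range(0, len(h1_seq) - step + 1, step):
        for hap, seq in (("H1", h1_seq), ("H2", h2_seq)):
            contig = {f"{hap}_contig{start // step:03d}": seq[start : start + step]}
            hits = tags.match_tags(contig, hap_tags, tags.TagConfig(cfg.k)) if hap_tags else []
            c1 = sum(h.group == "H1" for h in hits)
            c2 = sum(h.group == "H2" for h in hits)
            counts[next(iter(contig))] = (c1, c2)
    verdicts = haplotypes.assign_contigs(counts, cfg.min_hits, cfg.ratio)
    pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(out / "contig_assignments.tsv", sep="\t", index=False)
    correct = sum(v.verdict == v.contig.split("_")[0] for v in verdicts)
    done(phased_markers=len(phased), contigs=len(verdicts), correct=correct)

    # 6. Ks + divergence dating
    done = stage("divergence_dating")
    alignments = simgen.sample_gene_pairs(
        cfg.t_years, cfg.rate, cfg.n_genes, cfg.codons_per_gene, seed=cfg.seed
    )
    est, ks_table = molevo.date_pair("sim_a", "sim_b", alignments, cfg.rate)
    ks_table.to_csv(out / "ks_per_gene.tsv", sep="\t", index=False)
    done(median_ks=round(est.median_ks, 5), t_years=round(est.t_years, 1), genes=len(ks_table))

    # 7. gene trees + branch support
    done = stage("branch_support")
    codon_spec = simgen.GroupPhylogenySpec(
        cfg.support_newick, 60_000, cfg.rate, n_seqs_per_group=1, seed=cfg.seed + 1
    )
    codon_panels, _ = simgen.simulate_ancestral_groups(codon_spec)
    taxa = {g: seqs[0] for g, seqs in codon_panels.items()}
    gene_len = 2_000
    genes = {
        f"g{i:03d}": {t: s[i * gene_len : (i + 1) * gene_len] for t, s in taxa.items()}
        for i in range(min(30, 60_000 // gene_len))
    }
    global_tree = phylo.nj_tree(phylo.jc_distance_matrix(genes))
    gene_trees = [phylo.nj_tree(phylo.jc_distance_matrix(aln)) for aln in genes.values()]
    supports = phylo.branch_support(global_tree, gene_trees)
    phylo.support_table(supports).to_csv(out / "branch_support.tsv", sep="\t", index=False)
    (out / "global_tree.nwk").write_text(phylo.annotate_support(global_tree, supports) + "\n")
    (out / "gene_trees.nwk").write_text("\n".join(gene_trees) + "\n")
    done(gene_trees=len(gene_trees), branches=len(supports))

    report["headline"] = {
        "painting_accuracy": report["stages"]["paint_mosaic"]["accuracy"],
        "median_ks": report["stages"]["divergence_dating"]["median_ks"],
        "recovered_t_years": report["stages"]["divergence_dating"]["t_years"],
        "true_t_years": cfg.t_years,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
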