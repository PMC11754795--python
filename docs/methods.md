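# Methods

This note documents the models and procedures chromosaic implements, the
parameters that matter, the design decisions that were genuinely open, and
what the synthetic data do and do not establish about real-data behaviour.

## Ancestry painting

**Model.** An ancestry-diagnostic tag is a canonical k-mer (the
lexicographically smaller of the forward and reverse-complement spellings;
k odd so no k-mer is its own reverse complement) that occurs in at least
`min_group_freq` of one group's panel sequences and in zero sequences of
every other group, on either strand. Matching on assemblies is exact;
windows containing `N` yield neither tags nor hits. Hits are binned by
start coordinate into fixed windows; a window is labelled with the group
holding the maximum count iff the window's total count is at least
`min_hits` **and** the maximum is at least `ratio` of the total; otherwise
the window is `NA` (ties are `NA`). `NA` is a statement of insufficient or
conflicting evidence — it is distinct from an "unknown ancestor", which in
this framework is an ordinary group with its own panel and tags. Maximal
same-label window runs are merged into segments; breakpoint resolution is
therefore one window, with no sub-window refinement.

**Defaults and why.** k = 31 (a standard specificity/sensitivity
compromise for plant-genome k-mer analysis: long enough that cross-group
collisions are rare at percent-scale divergence, short enough to keep tag
density high), `min_group_freq` = 1.0 (a tag must be fixed in its panel),
window = 10 kb for the synthetic scale (100 kb is the analogous
genome-scale choice), `min_hits` = 5, `ratio` = 0.75. With ~1 diagnostic
31-mer per 2–3 bp at ≥1% inter-group divergence, the dominance rule is
saturated with evidence and the painting recovers truth segments at
window resolution. A `normalize_by_tag_count` flag divides each group's
window count by its total tag count before the dominance test, for
unbalanced panels; it is off by default because raw density is the signal
and the synthetic panels are balanced.

**Monotonicity.** Raising `min_hits` can only turn labelled windows into
`NA`, never the reverse; this is asserted as a property test.

## Trio phasing and haplotype parsing

A child heterozygote is phased when exactly one assignment of its two
alleles to (from-parent-1, from-parent-2) is compatible with the parental
genotypes — the classic rule that an allele absent from one parent must
come from the other. Sites compatible under both assignments stay
unphased; sites compatible under neither are flagged Mendelian-inconsistent
and excluded. Haplotype-specific tags are k-mers centred on each phased
marker, extracted from explicitly materialised haplotype sequences, so tags
spanning nearby markers carry the haplotype's alleles at every covered
site; tags arising in both haplotypes are removed, making the two tag sets
disjoint by construction. Contigs are assigned whole (chimeric contigs are
detectable from the per-window report but not split), with the same
dominance rule as painting over {H1, H2}; unassigned contigs are intended
to be carried in both haplotype assemblies. Genetic-map phasing is accepted
as pre-phased input (`source="map"`); no linkage-mapping engine is
included.

## Synteny blocks and ortholog groups

Similarity search is out of scope: the module consumes one-best-hit anchor
tables. Chaining is a dynamic-programming longest collinear chain — ranks
strictly monotone on both sides (increasing/increasing for `+` blocks,
increasing/decreasing for `-`), with each step's **combined** rank
displacement (A-side plus B-side) bounded by `max_gap` (default 10).
Bounding the combined step rather than each side separately prevents a
chain from skipping diagonally across a displaced or inverted run of
genes: bridging an m-gene inversion always costs a combined step of m + 1,
so inversions of `max_gap` genes or more always break a chain. Chains are
extracted best-first (longest first; ties prefer `+` orientation, then the
leftmost A-side start), each anchor joins at most one block, and blocks
below `min_block` = 5 genes are discarded. On small instances the result
is verified against an exhaustive depth-first chain search.

Blocks computed against a common reference are **associated** across two
assemblies iff strictly more than `min_shared` = 20 reference genes occur
in both (the strict reading of "more than 20"); association ignores block
orientation — only the shared-gene count matters — and is per block pair,
with no transitive closure. An ortholog group exists per reference gene;
an assembly contributes its paired gene iff every pair of blocks carrying
that reference gene (across the contributing assemblies) is associated.
Reference genes mapped to two different genes of one assembly are
conflicts and dropped with a warning. A `complete_occupancy` flag restricts
groups to those with a member in every assembly. Groups can be filtered to
those whose focal-assembly member's midpoint falls (half-open) in ancestry
segments carrying a target label — the mechanism for restricting a
phylogenomic analysis to regions of one ancestral origin.

## NG86 and clock dating

Synonymous sites per codon are counted by neighbour enumeration: per
position, the fraction of the single-nucleotide changes that are
synonymous, among changes not producing a stop codon (the denominator is
reduced when a neighbour is a stop); S + N = 3 per counted codon.
Differences in codons differing at d positions are averaged over the d!
orderings of single steps, excluding pathways through stop codons; the
rare pairs whose every pathway is blocked are dropped entirely. Codons
containing gaps, ambiguity codes or stops in either sequence are dropped
pairwise. Proportions pS = Sd/S and pN = Nd/N are corrected with the
Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged
saturated (d undefined, never clamped), and saturated genes are excluded
from the median. Stop-handling conventions differ between NG86
implementations; the convention above is asserted against an independently
written brute-force implementation (literal genetic-code table, explicit
neighbour and pathway enumeration) to 1e-12 on a thousand random
alignments — numerical parity with any particular external program is not
claimed. The genetic code defaults to the standard nuclear table and is
injectable.

Divergence dating is the molecular-clock relation T = median Ks / (2r)
with r = 4.5e-9 synonymous substitutions/site/year (the Musaceae average)
as the default; the median over genes uses the mean of the central pair at
even counts.

## Trees and branch support

Desk-scale tree inference is neighbour joining (via scikit-bio) on
Jukes–Cantor distances, exact on additive matrices; it stands
in for ML engines, which are deliberately out of scope. The support
statistic is independent of the inference method and accepts any newick
gene trees: for each internal bipartition of the global tree, support =
(gene trees containing the bipartition) / (gene trees where it is
evaluable), unrooted. Gene trees over taxon subsets are handled by
restriction: a bipartition is evaluable iff both sides still intersect the
gene tree's taxa; a bipartition that becomes trivial after restriction
(one side a singleton) is present in any tree and counts as supported —
the alternative (dropping such trees from the numerator only) would bias
support downward for taxa-poor gene sets. Polytomies support only the
bipartitions they actually induce. Placement testing scores the focal
taxon's sister set (its smallest non-trivial split side, minus itself) in
each gene tree against candidate sister sets restricted to shared taxa;
unmatched attachments accrue to `"other"`, and proportions sum to 1.

## Synthetic data

The generators emulate the study conditions rather than sequencing
reality:

- **Panels** evolve down a user-supplied clocklike tree (branch lengths in
  years) under Jukes–Cantor with exact per-branch transition
  probabilities, at 4.5e-9/site/year by default; panel depth defaults of
  4.4 and 7.8 Myr match the dated splits, and within-group diversity
  defaults to 0.1 Myr. JC rather than HKY85/GTR+Γ is deliberate: the
  downstream tests need clock linearity, not model realism, and the
  richer models parameterise inference engines that are out of scope.
- **Mosaics** concatenate donor slices at matched offsets (recombinant-
  style) and emit truth BEDs that provably tile the chromosome.
- **Rearrangements** (inversions, reciprocal translocations, applied in
  listed order with 0-based half-open breakpoints) are tracked as
  piecewise interval maps, giving exact bijective forward/inverse
  coordinate maps; inverted pieces are reverse-complemented.
- **Trios** draw recombinant gametes with explicit or Poisson crossovers
  and record the parental haplotype of every base.
- **Codon pairs** for the Ks chain place synonymous substitution *events*
  (Poisson with expectation 2·T·r per NG86 synonymous site per pair,
  targets uniform among a codon's synonymous single-nucleotide changes),
  so multiple hits and back-substitutions occur and the JC correction is
  exercised honestly, and no stop codon can arise. One caveat is inherent:
  two-fold degenerate sites toggle between two states, saturating on a
  2-state rather than 4-state trajectory, so JC under-corrects them
  slightly — an O(Ks/3) relative bias, under 2% at Ks ≈ 0.07 and far
  inside the 5% recovery tolerance. Seeds derive child streams by fixed
  offsets, so adding one generator call never perturbs another's draws.

What passing tests show — and don't. Truth recovery on these mosaics
demonstrates the painting logic (window assignment, NA behaviour,
breakpoint resolution) under clean divergence; real assemblies add repeat
content, missing data, collapsed haplotypes and panel contamination, none
of which are modelled (no indels, no sequencing error, no read-level
artefacts). Likewise the 100% trio-parsing accuracy is a correctness bar
for the logic at error-free genotypes, not an expected field performance.

## Problem sizes

Default desk-scale runs use 200-kb chromosomes, panels of 2 sequences per
group, 500 genes × 300 codons for clock recovery, and ≤10-taxon trees with
30–50 gene trees; these sizes give Monte-Carlo error comfortably below the
tolerances asserted (median-Ks standard error ≈ 1.3% at 500 genes) while
keeping any single test in seconds.

## Known limitations

- Exact matching only: diverged or repeat-rich regions shed tags and fall
  to `NA`; no approximate matching or minimizer indexes.
- Whole-contig haplotype assignment: recombinant (chimeric) contigs are
  flagged, not split.
- The chaining heuristic (best-first extraction of DP-longest chains) is
  deterministic but, like all collinearity chainers, not globally optimal
  on adversarial inputs; equivalence is asserted against exhaustive search
  on small instances only.
- NJ on JC distances is a desk-scale stand-in for likelihood tree
  inference; support and placement statistics are designed to consume
  externally inferred gene trees for real analyses.
- Coordinate maps are exact for substitution-only evolution; there is no
  indel model anywhere in the package.
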