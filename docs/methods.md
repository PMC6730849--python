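# Methods

## The analysis problem

A fused MAT locus is detected from three kinds of evidence in a haploid
assembly: (1) the pheromone/receptor genes and a single homeodomain gene on
one contig, tens of kb apart; (2) allele classes defined by the combination
of the STE3 variant (ancient **a**/α alleles) and the HD gene present; and
(3) population signatures of suppressed recombination — alleles clustering
by mating type rather than species, elevated between-mating-type synonymous
divergence, and AT-shifted composition of the region. Each module computes
one of these signals; the pipeline chains them.

## Synonymous divergence (NG86 + JC)

For each codon, the synonymous site fraction is the per-position fraction of
the three one-step mutations that preserve the amino acid; mutations creating
a stop codon count as nonsynonymous. For a codon pair differing at k ≤ 3
positions, substitution counts are averaged over the k! orderings of the
differing positions; orderings that pass through a stop codon are excluded
(if all are excluded, all orderings are used with stop-entering steps counted
nonsynonymous). Sites are averaged over the two sequences; proportions
pS = Sd/S and pN = Nd/N are corrected as d = −¾ ln(1 − 4p/3). p ≥ ¾ makes the
logarithm undefined; such estimates carry status `undefined` and print as
"Un". The codon alignment is protein-guided (global alignment of the
translations, back-mapped onto codons; gapped or ambiguous codon pairs are
dropped and counted), which preserves reading frame by construction.

Standard errors come from a seeded codon-resampling bootstrap (default
B = 1000; B = 0 disables). The SE is withheld when more than 10% of
replicates are undefined. This replaces an analytic variance because it is
distribution-free and directly testable.

With a transition/transversion ratio κ > 1 (the generator's default is 2),
NG86 is known to overestimate absolute dS somewhat, because the ⅓-per-position
site counting ignores the transition bias at synonymous sites. All uses here
compare dS between groups estimated the same way, so the bias cancels in the
contrasts; absolute values should be read with that caveat.

### Gene set for the between- vs within-mating-type test

The *t*-test compares per-gene dS of an A1-vs-A2 strain pair against an
A2-vs-A2 pair over core-region genes, excluding two classes of genes whose
inclusion would be meaningless: STE3 (its alleles diverged with the ancient
a/α split, orders of magnitude before any recent suppression) and SXI1/SXI2
(distinct genes, not alleles; when forced into a codon alignment their "dS"
is saturated/undefined). In pipeline runs the SXI exclusion also happens
naturally: reciprocal-best-hit ortholog pairing does not pair SXI1 with SXI2.
The test is one-sided (between > within), matching the directional
hypothesis that suppression accumulates divergence between mating types. No
multiple-testing correction is applied across genes; per-gene outputs are
descriptive.

## Alignment conventions

Protein global alignment is Needleman–Wunsch with BLOSUM62 and affine gaps
(open 11, extend 1); nucleotide local alignment is Smith–Waterman with
match +2 / mismatch −3, gap open 5 / extend 2 — the conventional BLAST
parameterizations, computed exactly (no seeding heuristics) via
Bio.Align.PairwiseAligner. A length-k gap costs open + k·extend. Reciprocal
best hits are decided on alignment score (length-aware); identity is reported
only for thresholds (defaults: score ≥ 50 and identity ≥ 0.25). STE3 typing
takes the class of the best-scoring reference; a margin below 5% of the best
score is unresolved. The conserved α-group N-terminal proline, when
identifiable in the references, is reported as an advisory flag only.

## Synteny blocks and windows

Anchors are reciprocal-best protein pairs positioned at gene midpoints;
orientation compares annotated strands. Blocks are greedy maximal runs of
constant orientation with monotone partner position (increasing for
colinear, decreasing for inverted); greedy maximal runs minimize the number
of runs, and tests verify equality with an exhaustive minimum-partition
oracle. Runs below `min_anchors` (default 2) are reported as singletons, not
blocks, so single-gene transpositions are not called inversions. Breakpoint
intervals are the open gaps between the outermost anchors of adjacent
blocks. Window similarity tiles the query into non-overlapping fragments
(default 1000 bp; fragments under 100 bp are rejected as degenerate) and
records the best local-alignment score against the target, both strands.

## Statistics

The Mann–Whitney U statistic uses midranks. For n₁·n₂ ≤ 400 the one-sided
p-value is exact: the permutation null of the rank sum is enumerated by
dynamic programming over the (doubled) midrank multiset, which is correct
under ties. Larger samples use the normal approximation with continuity and
tie corrections (scipy). The dS comparison uses the pooled-variance Student
*t* with a one-sided alternative; a degenerate zero-variance case returns
t = 0, p = 0.5 when means are equal. Type-I error of both tests is verified
at α = 0.01 and 0.05 over 2000 null replicates.

The breakpoint-divergence ("suspension bridge") test classifies windows as
*breakpoint* (overlapping a breakpoint interval, ± `flank_windows` windows)
or *interior* (inside an inverted block) and applies the one-sided rank-sum
test that breakpoint similarity is lower. Three windows per class are the
minimum.

## Genealogies

Distances are p-distances with pairwise deletion of gap/ambiguity columns,
optionally JC-corrected (undefined and flagged at p ≥ ¾). Trees are built by
Saitou–Nei neighbor joining with the standard Q criterion, deterministic
tie-breaking by smallest label pair, and negative branch lengths clamped to
zero with the deficit moved to the sister branch; additive matrices are
recovered exactly (verified to 1e−9 on random 8-taxon trees). Neighbor
joining is used instead of likelihood tree inference because the
classification consumes only the topology, which NJ recovers at the
divergence levels involved, and it is deterministic and oracle-testable.

Classification works on the unrooted tree's bipartitions: *mating-type* if
some bipartition separates exactly the A1-class tips from the A2-class tips
(a single-tip class is trivially separated, so panels should carry at least
two strains per class for an informative call — the pipeline skips
incomplete ortholog families for this reason); *species* if no such
bipartition exists and every multi-tip species is separated by some
bipartition; otherwise *mixed*.

## Composition

GC is reported in percent; ambiguity codes are excluded from numerator and
denominator. Window tracks tile from the region start; the trailing partial
window is emitted but flagged, and excluded from tests by default. The
base-count-weighted mean of window values equals the whole-sequence GC
exactly (a conservation identity tested on arbitrary inputs). RSCU is the
observed codon count divided by its synonymous-family mean, so family means
are exactly 1 where the family is observed; single-codon families (Met, Trp)
are 1 by convention and unobserved families are absent rather than
zero-divided. Region-vs-genome contrasts use the rank-sum test; in the emulated analyses
the GC contrast is presented visually, so attaching a named test is a
design choice of this package. Codon-usage comparisons use RSCU rather than
raw frequencies to control for amino-acid composition.

## The synthetic-genome generator

Each strain is a haploid genome: one MAT contig (left flank genes, the core
MAT region, right flank genes) plus background contigs. The core template
carries the pheromone gene (MF) and STE3 at one end, STE20/IKS1/STE11/MYO2/
RPL22 and filler genes in the middle, and the HD gene at the far end. Gene
lengths are uniform 900–2400 nt (MF: 3·(spacer+6) nt), intergenic gaps
uniform 200–1800 nt, which puts the expected STE3-to-HD gap at ~54–56 kb,
the separation the detector is meant to report. A2-class strains carry the
template rearranged by two inversions (default segments: genes 2–17, i.e.
most of the core region, and 19–21); an inversion reverses block order and
reverse-complements the sequence, so junctions fall in the boundary
intergenic gaps and truth records exact breakpoint intervals.

Sequences evolve by an HKY-style substitution process (equilibrium GC split
evenly within {G,C} and {A,T}; κ default 2.0; branch lengths in expected
substitutions/site) down a Yule species tree scaled to height 0.15, with
every speciation conditioned (by resampling) to predate the present by at
least 0.05 — species panels in this field are separated by millions of
years, far older than within-species polymorphism, and without that
condition a freshly split species pair would be indistinguishable from
strains of one species. Strains attach to their species tip with branches of
0.025, giving within-species pairwise divergence 0.05, the scale of the
within-mating-type dS the trio analysis expects. CDS evolve under a
constraint fixer that reverts mutations creating internal stops or
destroying the start/stop codon; the pheromone gene additionally keeps its
consensus positions and avoids in-frame internal ATGs so the planted
precursor stays a single unambiguous ORF. Indels are not simulated, keeping
truth coordinates exact and ortholog alignments trivial.

Planted signals and their defaults:

* **STE3 trans-species polymorphism** — the gene splits into a and α
  ancestral alleles at depth 0.5 (≫ tree height); A1-class strains carry α,
  A2-class a.
* **SXI1/SXI2** — independent random genes of equal length; carried per
  allele class (A1→SXI2, A2→SXI1, starred classes the reverse).
* **Recombination suppression** — `mat_suppression_extra` (default 0.02
  substitutions/site, a free choice: no quantitative magnitude is reported
  for the real system) is added between the two mating types of each
  species, confined to core-MAT genes; within-class divergence is untouched.
  With `homogenize_inversions`, breakpoint-adjacent genes instead get
  `breakpoint_extra` (0.05) and inversion-interior genes none, emulating
  gene-conversion homogenization inside inversions.
* **Composition** — core MAT evolves and is rooted at equilibrium GC 0.52
  vs background 0.60 (an 8-point depression; genomic GC in the emulated
  clade is 58–63%).

The reference panel shipped with a simulation is built from the ancestral
(root) protein sequences of the named MAT genes, with both STE3 allele
ancestors tagged `class=a` / `class=alpha`.

### What the generator does not emulate

Real assemblies have indels, introns, repeats, assembly gaps and annotation
errors; orthologs differ in length; species trees are not ultrametric in
substitutions. Passing the truth-recovery tests therefore shows the
detectors are correct on clean planted structure at realistic sizes and
divergences — not that they are robust to annotation noise or repeat-rich regions, which
real analyses handle with curation and repeat masking.

## Problem sizes used in tests and the acceptance script

Simulated panels use 2–3 species with 2–3 strains each, one ~70 kb MAT
contig (23 core genes) and 1–2 background contigs of ~10 genes — large
enough for every statistic's asymptotics (20+ genes per dS set, 25+ GC
windows per class) while keeping a full dataset under a quarter second.
Replicate counts: 100 allele pairs for inversion recovery, 50 trios per arm
for the suppression test and its null, 20 datasets for trans-species
recovery, 50 for composition, 2000 nulls for test calibration; the
acceptance script uses one full pipeline run plus 12-replicate detection
rates, and the window-similarity track is computed over a bounded slice of
the core region (`similarity_max_kb`) because exact Smith–Waterman over the
full 60 kb × 60 kb region adds nothing but runtime.

## Known limitations

* NG86/JC rather than a codon-model likelihood: absolute dS inflated under
  transition bias (see above); adequate for the contrasts computed here.
* The exact rank-sum enumeration conditions on the observed midranks;
  p-values are mildly conservative under heavy ties.
* Hybrid (two-subgenome) assemblies are split by contig and reported per
  subgenome candidate; no phasing is attempted.
* Unlinked HD/P-R configurations report no distance (no convention exists
  for inter-contig distances).
* The pheromone consensus is permissive; genome-scale scans yield chance
  ORF candidates (a few per 100 kb), so candidate lists are meant to be
  intersected with annotation or synteny context, as the pipeline does.
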