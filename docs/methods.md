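# Methods

This note documents the models, decision rules, numerical choices and
limitations behind each `dupfate` module. Defaults given here are the
package defaults; every threshold is configurable through the module
functions and `PipelineConfig`.

## Duplication detection on gene trees

Gene trees are rooted, with aLRT branch supports in [0, 1] stored at the
internal-node label position of the Newick string, and leaf names encoding
the species (`SPECIES_geneid`; the species extractor is a configurable
regex, and an explicit gene→species TSV can override it).

**Species overlap.** An internal node is labelled *duplication* iff the
species sets of its daughter partitions intersect; for multifurcations the
daughter partitions are compared pairwise and any intersecting pair makes
the node a duplication. This reconciliation-free rule is robust to missing
taxa but will miss duplications in which one copy's descendants were
entirely lost.

**Events and fusion.** Species-specific duplication events are the maximal
clades whose leaves are all (and at least two) focal-species genes. Two
events fuse when they share more than 50% of the *smaller* event's members
(the denominator is not forced by the verbal rule; the smaller event is
the symmetric, conservative choice). Fusion is iterated to a fixpoint —
merged events are re-examined against the rest — which makes the operation
idempotent; a single connected-components pass over the original events
would not be, since merging enlarges events and can create new qualifying
overlaps.

**Pair selection.** A pair requires duplication-node support strictly
greater than 0.95 and single-copy orthologs (species other than the focal
one represented by exactly one gene in the tree) in at least two species.
Nodes without a parseable support are skipped with a logged warning rather
than an error. For events with more than two members, only sister tips
(cherries) are paired, because internal pairings of an expansion would mix
duplication ages. Pairs whose orthologs all lie in the three most distant
taxa (*D. citri*, *B. tabaci*, *D. vitifoliae*) are discarded: synonymous
distances to these species are close to saturation and orthology is least
reliable there. A retention check against an independently re-estimated
tree passes iff the MRCA of the two copies still contains only
focal-species leaves; it deliberately re-checks topology only, not
support.

**Duplication ratios.** A duplication node maps to the species-tree MRCA
of its descendant species. A gene tree "contains" a species-tree node when
it samples at least one species from each daughter partition of that node
(for tips, when the species is present), i.e. when the node would appear
in the induced species tree. The ratio is duplications mapped to the node
divided by containing trees.

## Branch rates and selection

**Why counting, not ML.** Free-ratio and branch-site codon-model
optimization is out of scope; the package estimates per-branch rates with
a transparent counting chain — Fitch parsimony ancestors plus Nei–Gojobori
(1986) — and ingests branch-site (and MNM-aware branch-site) p-values
computed by external ML software as TSV. Every downstream decision rule
(fast/slow, dS filters, the adjusted-p selection call) operates
identically on either source of rates. Counting estimates are biased
toward each other on short branches (the parsimony ancestor absorbs part
of each branch's changes), so absolute omegas are compressed; the pipeline
only ever uses orderings and thresholds on dS, which the simulation
experiments show are recovered in ≥ 99% of pairs under planted
fast (ω = 1.5) / slow (ω = 0.1) regimes at 200 codons.

**NG86 conventions.** Synonymous sites per codon are the fraction of the
nine single-nucleotide changes preserving the amino acid; changes creating
stop codons count as nonsynonymous sites, so S + N = 3 per codon and the
two site totals are averaged over the two sequences. Observed differences
are averaged over all mutational pathways between two codons, excluding
pathways through stop codons (all pathways are used if every one is
blocked). The Jukes–Cantor transform −(3/4)·log(1 − 4p/3) saturates at
p ≥ 0.75; saturated rates are reported as infinite, flagged, and routed to
the dS > 2 exclusion path. omega is undefined (flagged, excluded from
summaries) when dS = 0.

**Fitch details.** Parsimony operates on whole codons over the
outgroup-rooted ladder ((pair), out1), out2, …. In the top-down pass a
node takes its parent's state when the up-pass set allows it, else the
lexicographically smallest member. "Unresolved" counts only codons that
needed the lexicographic fallback — ambiguous up-pass sets that the parent
resolves are the normal case wherever the two copies differ — and an
error is raised when more than 50% of codons are unresolved.

**Filters and calls.** The dS age filters retain 0.01 ≤ dS ≤ 2
(boundaries inclusive: the stated exclusions are strict inequalities); the
pair-level variant drops a duplication if either copy fails. The slow copy
is the argmin of post-duplication dS, ties broken lexicographically and
flagged. P-values are adjusted by Holm, Hochberg, Šidák single-step, Šidák
step-down, Benjamini–Hochberg and Benjamini–Yekutieli (delegated to
statsmodels; unit tests verify all six against hand-rolled step formulas),
and a gene is called selected when the minimum adjusted p over the six
methods is < 0.01. MNMs are codons differing from the reconstructed
ancestor at ≥ 2 positions, reported as a percentage of codons compared.

## Family and location classes

Strict duplicates are fused events with exactly two members; anything
larger is an expansion. Tandem means same contig and adjacent rank, where
rank is the ordinal position among *all* annotated genes on the contig by
start coordinate regardless of strand — the only strand-free reading of
"no genes in between" — so a nested or overlapping gene does break
tandemness. Retrocopies are dispersed pairs in which exactly one copy is
intronless; a dispersed pair with both copies intronless is ambiguous
(the mRNA-derived copy cannot be identified) and is flagged for review
instead of being called a retrocopy.

## Expression profiles and divergence

TPM is FPKM normalized to a column sum of 10⁶. Each library is
quartile-binned independently: cut points are the 25/50/75th percentiles
with linear interpolation (the common quantile default), assignment uses ≤
on the cut points, and a constant column degenerates to all-bin-1 with a
flag. Replicates collapse by strict majority (> 50% of the condition's
libraries on one bin; a 50/50 tie gives NA). Binarization maps bin 1 → not
expressed, bins 2–4 → expressed.

All three divergence statistics are restricted to conditions observed in
both genes (the NA rule stated for the Hamming distance, extended to TEC
and dT for consistency): Hamming = differing/considered; dT =
(|either| − |both|)/|either|, NA when neither gene is expressed anywhere;
TEC = max over the two genes of (conditions expressed exclusively in that
gene)/(conditions expressed in that gene), NA when either gene has an
empty expression set, with a "mean" combination available behind an
option. Gains and losses compare the selected copy against the
non-selected copy's profile on jointly observed conditions. Cross-tissue
correlations use per-condition median TPM over replicates, per-gene
min–max rescaling to [0, 1], Pearson r with its p-value, and the
least-squares slope of copy B on copy A; zero variance in either rescaled
vector yields NA with a degenerate flag.

## Chromatin state at the TSS

Both coverage tracks are scaled to equal totals (sequencing-depth
normalization), averaged in 10-bp bins, and combined as
log2((F + 1)/(I + 1)) with a pseudocount of 1; bins with no coverage in
either track are absent (NaN), not zero. The TSS window is 900 bp centered
on the strand-aware gene start (the annotated start on +, the annotated
end on −; strand-unaware anchoring is available behind a switch since
naive genome-browser usage is often strand-blind), clipped to the contig,
with bins weighted by overlap and the covered fraction recorded. Open
means mean signal ≥ 1 — the boundary value itself is called open, a
documented choice where the rule only defines above/below. Joint
categories (open/closed × expressed/not) are assigned per condition where
both data types exist; the gene-level category requires ≥ 75% agreement
among informative conditions, otherwise the gene is unassigned. A pair has
"different chromatin" iff some shared condition calls one copy open and
the other closed.

## Tajima's D and codon adaptation

Pooled site counts are subsampled without replacement (multivariate
hypergeometric) to exactly 15 reads; sites with coverage below 15 or above
150 are discarded. Tajima's D then uses the classic constants with
n = 15: D = (π − S/a₁)/√(e₁S + e₂S(S−1)), undefined (NA) when S = 0.
The pool-size-corrected estimator of pooled-sequencing toolkits is *not*
re-implemented: with a fixed subsampling target the classic statistic
differs only in a monotone calibration, and the analysis uses D
comparatively (exons vs introns, gene subsets), never its absolute value.
The pool sizes of the source populations are carried as metadata only.

CAI is the geometric mean of relative adaptiveness w (codon usage divided
by the maximum within its synonymous family), excluding stop codons and
single-codon families (Met, Trp); zero-usage codons floor w at 0.01 with a
flag. The expected CAI is the 95th percentile (configurable) of CAI over
1,000 random sequences of matched codon count and mononucleotide
composition with stop codons resampled, and a gene is "optimized" iff
CAI > eCAI.

## Synthetic data: what it does and does not emulate

Generators are deliberately minimal and fully seeded (one
`numpy.random.Generator` drives each run; identical seeds give
byte-identical outputs).

* **Gene trees** place a terminal caterpillar of 2–3 focal-species copies
  on the 9-taxon reference topology with high support (0.99) on planted
  duplication nodes. There is no gene loss, no deep paralogy and no
  topological noise, so noise-free detection recall and precision are 1.0
  by design — passing this says the rule chain is implemented correctly,
  not that detection is robust to real phylome noise.
* **Codon alignments** evolve by single-nucleotide proposals at a rate
  proportional to branch length, transitions weighted κ = 2, synonymous
  proposals always accepted and nonsynonymous with probability ω (for
  ω > 1 the proposal rate is inflated and acceptances rescaled so the
  synonymous rate is unchanged); stops are rejected. No rate
  heterogeneity, no indels, no codon-frequency bias.
* **Expression matrices** plant binary profiles directly: expressed cells
  get a gene base level (uniform 20–200) times a per-condition activity
  shared within the pair (so same-profile pairs correlate across
  conditions, as real paralogs do), not-expressed cells are exactly zero,
  and a filler population (35% silent) anchors the per-library quartiles
  so the lowest quartile recovers planted zeros exactly in the noise-free
  case. Replicate noise is optional log-normal. Real RNA-Seq dispersion,
  mapping ambiguity between close paralogs, and library-size effects are
  not modelled — the statistics' decision thresholds are exercised, their
  robustness to those effects is not.
* **FAIRE tracks** are uniform Input with 4× FAIRE enrichment over planted
  open TSS windows; after depth normalization open windows sit near
  log2 ≈ 1.9 and closed near −0.1, cleanly separated by the threshold
  of 1. No fragment-level noise or peak-shape structure.
* **Coalescent samples** come from msprime (ploidy 1, N = 1, continuous
  genome, mutation rate θ/2 per unit locus), giving E[π] = θ under the
  standard neutral model. The acceptance band for the 2,000-replicate
  neutral mean of D is ±0.15, which accommodates the known small negative
  bias of E[D] at n = 20 (the statistic is not exactly centered on zero).

## Problem sizes and determinism

The default end-to-end configuration (40 trees, ~50% planted, 200 codons,
3 replicates × 18 conditions, 3 FAIRE conditions) runs in a few seconds
and was chosen so the complete chain — including 200-pair rate-recovery
and 2,000-replicate calibration experiments — stays desk-scale while every
decision rule is exercised with non-trivial counts. TSV outputs use fixed
float formatting (`%.6g`); reruns with the same config and seed are
byte-identical, which the test suite asserts.

## Known limitations

* Counting-based rates compress omega toward 1 relative to ML estimates;
  only orderings and dS thresholds should be interpreted.
* The species-overlap rule cannot see duplications erased by differential
  loss, and the fusion denominator ("smaller event") is a documented
  choice, not a derived one.
* TEC's symmetrization (max vs mean) changes values for asymmetric pairs;
  the default is max.
* Classic Tajima's D on subsampled pools is a relative, not absolute,
  measure here.
* The synthetic generators validate decision logic, not robustness to the
  noise structure of real sequencing data.
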