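# Methods

`ploidyscan` infers paleopolyploidy from gene colinearity. This note
describes the models and procedures each module implements, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical choices and known limitations a user should be aware of.

## The inference chain

Homologous gene pairs (a 12-column tabular hit list screened at
E ≤ 1e-5) are chained into colinear blocks on gene-rank coordinates;
per-pair synonymous divergence (Ks) dates each block; mixtures of
Gaussian components summarize Ks samples; corrected peaks are converted
to ages against a calibrated reference event; block depths over a
reference genome read out ploidy; alignment tables quantify
fractionation; and per-locus gene trees expose the rate distortions that
can mislead naive phylogenetics.

### Colinearity detection

Blocks are maximal chains of hit pairs strictly monotonic in rank on
both chromosomes (parallel or antiparallel), with neighboring pairs
separated by at most `max_gap = 50` gene ranks on each side and at least
`min_pairs = 4` pairs — the thresholds conventional in plant comparative
genomics. Chaining is an O(n²) sparse dynamic program maximizing pair
count, ties broken by smaller total rank span, then by the
lexicographically smallest first pair; chains are extracted greedily,
best first, each hit consumed by at most one block per chromosome pair,
while a gene may still anchor blocks on other chromosome pairs (without
this, outparalogy depth would be invisible). Tie choices are
deterministic but not invariant under swapping the two genomes; on
instances with equally scoring alternatives the A→B and B→A block sets
can differ in membership while always agreeing in number and lengths.

Significance uses a Poisson chain-count model: with hit density λ over
an `la × lb` chromosome pair, the chance a hit extends within its gap
window is `q = 1 − exp(−λ g²)`; the expected number of maximal chains of
length ≥ k is `E = 2 n (1 − q) q^(k−1)` (two orientations, any start
with no predecessor) and `p = 1 − exp(−E)`. Above the percolation point
`λ g² ≥ 1` long chains exist almost surely and the maximality factor is
dropped, which correctly drives p toward 1 in saturated backgrounds. The
model was validated against permutation nulls; it is accurate to within
a factor of ~2–3 in the subcritical regime where block calling operates,
and conservative elsewhere.

### Ks estimation and mixture fitting

Coding pairs are aligned through their protein translation (global
alignment, BLOSUM62, gap open −10 / extend −0.5) and back-translated to
codons; gap columns are excluded. Nei–Gojobori (1986) counting follows
the standard conventions: per-codon site fractions from single-step
neighbors normalized to three sites per codon, mutations to stop codons
counted as nonsynonymous, observed differences averaged over all minimal
mutational pathways (pathways through stop codons are traversed, their
steps scored nonsynonymous), and the Jukes–Cantor correction
`d = −(3/4) ln(1 − (4/3) p)` applied to both proportions. Proportions at
or beyond 3/4 are flagged saturated (Ks undefined) and excluded from
fitting. The implementation agrees with Biopython's NG86 to four
decimals on random codon pairs.

A Ks sample is summarized by a fixed-bandwidth (0.05) Gaussian kernel
density on 300 grid points over [0, 3]; values above 3 are discarded as
saturated noise. Gaussian mixtures with 1..4 components are fit to that
density by least squares (peak-seeded initialization), and the smallest
component count reaching R² ≥ 0.95 is kept; the heaviest component
represents the underlying event. Fitting the density rather than
running EM on raw values mirrors the kernel-plus-curve-fit practice this
analysis style established. Block median Ks uses the even-count
convention (mean of the central two).

### Rate correction and dating

Lineages run at different synonymous clocks, so one event leaves
different peaks in different genomes. Step 1 multiplies each lineage's
Ks by `c1 = μ_grape / μ_lineage`, where the μ are the fitted peaks of the
shared ancient hexaploidization in each genome and grape (the slowest
lineage) is the reference; cross-genome samples use the algebraic mean
of the two coefficients. Because the cotton lineage accelerated again
after its own polyploidy, step 2 multiplies all cotton-lineage samples
by `c2 = μ_durian–outgroup / μ_cotton–outgroup` computed from the
step-1-corrected ortholog distributions against cacao. Corrections are
applied to whole samples, so refitted distributions (not just means)
align; they are multiplicative, hence order-preserving, and a second
pass computes coefficients of 1.

Event ages scale linearly: `date = peak / peak_ECH × [115, 130] mya`.
The calibration peak is a parameter (the grape shared-event peak,
~1.04 in the synthetic geometry).

A structural property worth knowing: when the rate elevation is confined
to the cotton branch after the cacao split — the only place a
lineage-specific rate can live in a consistent joint gene tree — the
two-step correction retains a positive bias of factor
`4 r c1 / ((1+r)(1+c1))` on the cotton event's peak, because the
cross-genome peak that defines c2 dilutes the elevation with the
outgroup's unelevated half-path. At the synthetic geometry (splits at
one-way Ks 0.125, shared event at 0.52, r = 1.64) a true peak of 0.12 is
recovered as ≈ 0.139, still within ±0.02, and its date range shifts a
couple of Myr older than the truth. The durian event, whose lineage runs
at the grape clock, is recovered without bias.

### Ploidy profiling

Blocks between a reference and a target are labeled by median Ks:
orthologous below `ortholog_max`, outparalogous above `outparalog_min`,
ambiguous between (defaults 0.95 / 1.30 for a grape–durian-like
comparison; 0.85 / 0.95 for the synthetic scenarios whose true ortholog
and outparalog peaks sit near 0.5 and 1.2). The reference is cut into
20-gene windows; per window the number of distinct target regions whose
orthologous (resp. outparalogous) blocks overlap it is counted, after
merging complement blocks produced by chromosome breakage (same target
chromosome and orientation, reference intervals within 25 ranks). The
mode over non-empty windows is the orthology (outparalogy) ratio: a
haploid reference region with three orthologous target regions means the
target tripled after the two lineages split. Window-mode counting makes
the visual "count the diagonals" reading of a dotplot reproducible and
robust to moderate gene loss (the modal 1:3 survives retention 0.7 on
≥80% of seeds).

### Fractionation and the shared-ancestry statistic

Ortholog blocks are phased into subgenome columns by greedy interval
coloring (longest block first; overlapping reference intervals get
different columns), giving a reference-gene × column table per target.
The missing fraction is the share of reference genes with no surviving
colinear gene in any column of a target. For two polyploid targets the
column-overlap similarity `|filled in both| / |filled in the second|`
over all column pairs distinguishes histories: subgenomes that
fractionated together before the lineages split keep near-identical fill
patterns (best-match similarity near 1, large best-minus-secondary
margin), while independent polyploidies give low, near-uniform values
around the fill rate.

### Gene-tree distortion

Homolog groups (one grape outgroup gene, one cacao gene, ≥3 cotton, ≥2
durian genes sharing a locus) get distance trees: p-distance (optional
Jukes–Cantor), native neighbor-joining or UPGMA, grape rooting, supports
from 100 seeded alignment-column bootstrap replicates. Trees are typed by
the cacao gene's sister set: A if it is the whole cotton+durian
complement (the expected history), B if exactly the durian cluster, C if
exactly the cotton cluster, D otherwise; the classifier is total over
all 945 rooted shapes at minimal group size. The cluster pattern over
branches with ≥70% support distinguishes species clusters (independent
events) from one-to-one cotton–durian cherries (a shared event).

Distortion behavior is non-monotone at the extremes: with homogeneous
per-edge rates and long sequences, distances stay tree-additive and NJ
is simply consistent; under very strong saturation the slow cacao gene
is attracted to the grape outgroup, which the typing scheme still reads
as "expected". The regime that reproduces the misplaced-cacao
distortion is moderate, asymmetric elevation (durian mildly, cotton
strongly accelerated) with realistic sequence lengths, where non-A
fractions rise steeply with the rate ladder (≈0.16 → 0.43 → 0.52 across
(1,1) → (1.5,3) → (2,5) at 80 codons).

## The simulator

The generator walks the fixed phylogeny
`(grape,(cacao,(durian,cotton)))` with branch lengths in expected-Ks
units (one-way synonymous substitutions per site at rate 1) and
per-branch rate multipliers. Whole-genome multiplications are placed on
branches (the shared hexaploidization on the stem above the root);
every post-event duplicate survives with probability `retention_prob`
except the parental copy, which is always kept so no locus vanishes;
optional terminal fractionation (`terminal_loss_prob`) continues losing
duplicates lineage-specifically at the tips, never below one copy per
locus. Tandem duplicates insert at adjacent ranks (at branch midpoints,
so pairs accumulate divergence); segmental inversions reverse random
rank intervals and flip strands.

Sequences are codons from the six fourfold-degenerate families with
fully nonsynonymous first/second positions (Val, Ser, Pro, Thr, Ala,
Gly). Third positions evolve by exact Jukes–Cantor transition sampling
at the branch's realized Ks length, first/second positions by a Poisson
number of nonsynonymous family moves at `omega = 0.2` of that rate,
constrained inside the family set; no stop codon can ever arise and the
synonymous site count is exactly one per codon, making the expected
estimated Ks of a pair equal to the true rate-scaled path length
separating them. Genes sharing history share the corresponding
evolution, so the realized process is a proper gene tree.

Simulated hit tables list every true homolog pair with identity
`100·(0.45 + 0.55 e^{−d})` plus N(0, 0.5) noise and an E-value
decreasing with identity, capped at 1e-6 so everything passes the
screen. Scenario presets encode the study conditions: `ech_only`,
`ech_wgd`, `ech_dsh`, `ech_dsh_gsd` (zero-loss model-prediction runs at
200 ancestral genes, 2 chromosomes, 200 codons, splits at one-way depths
0.25/0.15/0.12, shared event at 0.60, lineage events at 0.08/0.05),
`rate_recovery` (equal split depths 0.125, shared event at 0.52, cotton
×1.64) and `study` (retention 0.5, tandems, inversions, cotton ×3 —
peaks land near 1.19 grape, 0.22/1.35 durian, 0.30/1.70 cotton).

What the simulator does **not** emulate: real fractionation bias between
subgenomes, tandem arrays longer than pairs, translocations between
chromosomes, among-site rate variation, codon-usage and transition/
transversion bias, alignment error, and spurious (non-homologous) BLAST
hits. Tests passing on this generator therefore demonstrate the
*inference machinery* — chaining, estimation, mixture fitting,
correction algebra, depth counting, tree typing — not robustness to
every artifact of real annotations.

## Numerical choices and degeneracies

* Colinearity ties: deterministic (span, then lexicographic) but not
  transpose-symmetric; see above.
* Mixture fitting: component sd bounded in [bandwidth/4, 3]; weights
  reported normalized; an unreachable R² target returns the best fit
  flagged `converged=False` rather than raising.
* Exactly-at-threshold block medians are ambiguous (excluded from depth
  counting), matching a strict reading of "below/above".
* Saturated pairs are excluded from all fitting; a block whose pairs are
  all saturated has undefined median and is ambiguous.
* NJ ties (equal minimal Q) are resolved by index order; at four active
  nodes the complementary pair ties exactly by the Q identity and either
  join yields the same topology.
* Dating of a peak older than the calibration warns rather than fails.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns (history, sequences, hit noise),
  so identical configurations are byte-identical across runs.

## Problem sizes

Default test and acceptance runs use 120–200 ancestral loci on 2
chromosomes with 200-codon genes, chosen so every scenario's block
structure (up to 54 full-length grape–durian blocks, ~27k durian–cotton
pairs) is populated well enough for stable mixture fits while a full
analysis completes in minutes on one CPU. The analysis drivers under
`analysis/` use 150 loci.

## Known limitations

* The cotton-event peak retains the correction bias described above;
  its dates should be read as upper-bound-shifted by ~15%.
* The significance model is approximate near the percolation point.
* Subgenome column phasing is greedy; with heavy rearrangement a column
  can mix subgenomes across distant reference segments, diluting (never
  inflating) the shared-ancestry similarity signal.
* Only NJ and UPGMA are implemented; likelihood and parsimony methods,
  which the distance-based distortion analysis stands in for, are out
  of scope.
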