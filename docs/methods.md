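# Methods

This note documents the models and numerical choices behind `satdna`: what
each statistic means, how the synthetic generator is calibrated, and what
passing the test suite does and does not establish about real data.

## Alignment and identity conventions

All identity-bearing results use linear scoring (match +1, mismatch −1,
gap −2, no affine extension) — adequate at the 40–180 bp monomer scale —
and the p-distance convention: identity = matches / comparable columns,
where columns with a gap in either row are excluded (pairwise deletion).
The alternative policy (gaps count as mismatches) is selectable everywhere
via `gap_policy`.  Ties among equal-scoring alignments are broken
deterministically (diagonal over gap-in-`b` over gap-in-`a`), and
`pairwise_identity` aligns a canonical representative of the pair so that
it is exactly symmetric and reverse-complement invariant even when
co-optimal alignments differ in match count.

Wraparound alignment treats the consensus as circular: the DP state is
(read prefix, consensus phase), the start phase is free, and horizontal
(gap-in-read) moves are relaxed cyclically within each row — two sweeps
suffice because the gap penalty is negative.  Origin traversals of the
traceback are the monomer boundaries; flanking partial monomers get
fractional completeness (consensus columns covered / consensus length),
and monomers from the reverse strand are stored reverse-complemented, i.e.
in consensus orientation, so that ordinal adjacency is meaningful after
strand normalization.

Equal-length, indel-free monomer sets are analyzed as a direct row stack
rather than re-aligned: at ~20 % column divergence a star alignment
occasionally inserts compensating gap pairs that shift register and
spuriously break conserved columns.  Star alignment to the anchor
consensus is the route for monomers of unequal length (the read-extraction
pipeline), with insertions merged per anchor position.

## Period detection and harmonics

`score(p)` is the matching-base fraction between the sequence and itself
shifted by `p`.  The reported period is the smallest `p` scoring within
ε = 0.02 of the maximum (suppressing 2×/3× harmonics), then refined to its
smallest divisor still above the score threshold.  The refinement matters
for dimeric HORs: the profile peaks at twice the monomer (within-class
identity, here ~0.89) with a lower plateau at the monomer itself
(between-class identity, ~0.69), and the monomer is the right unit to
report; the suppressed multiple is flagged as a harmonic.

## Restriction ladders

Digestion scans the forward strand with IUPAC matching (the screening
battery is palindromic, so this finds every double-stranded site); cut
offsets default to 0 since only fragment lengths enter the ladder logic.
Ladder inference grid-searches candidate units; `support(u)` is the
fraction of fragments within tolerance of an integer multiple of `u`.
Every proper divisor of the true unit fits the grid at least as well
(59 = 177/3 ties exactly on clean data), and a stray fragment can hand a
divisor strictly *higher* support, so the winner is chosen
anti-harmonically: among units within 0.05 of maximal support, those with
(near-)minimal mean grid deviation are kept and the largest wins.  Maximal
support below 0.5 is reported as "no ladder"; defaults (u ≥ 30 bp,
tolerance 3 bp) keep the chance support of random fragments near
(2·tol+1)/u ≈ 0.2, well under that cut.

## HOR inference

A monomer is eligible when an adjacent monomer (same read, ordinal ± 1) is
in the set.  Its nearest neighbour is the highest-identity other monomer,
with ties broken *toward* adjacency — the conservative direction: on
divergence-free data every comparison ties and the non-contiguous fraction
is exactly 0, so homogeneous families cannot spuriously signal HOR.  The
two-class partition is average-linkage agglomerative clustering on
`1 − identity` cut at two clusters; order 2 is called when the
non-contiguous fraction exceeds 0.5, the between-class identity is below
both within-class identities, and adjacent same-read pairs alternate
classes more than 70 % of the time (all thresholds configurable).  The
fixed two-class partition is deliberate; higher-order HORs are out of
scope.

Note that the non-contiguous fraction saturates near 1.0 on a clean
alternating dimer — "about 60 %" in real data reflects homogenization and
heterogeneity a clean two-class model does not produce (see Limitations).

## Trees and bootstrap

Neighbor joining follows Saitou–Nei with lexicographic tie-breaking at
every argmin (bit-reproducible trees); negative branch lengths are clamped
to zero with the deficit recorded, not redistributed.  Bootstrap is
classical Felsenstein column resampling, implemented as multinomial column
weights entering the weighted p-distance computation; supports are mapped
onto the original tree's bipartitions only.  A label is "supported" when
some internal edge's bipartition equals exactly that label's leaf set at
support ≥ 70 %; labels on < 2 leaves or on all leaves are not assessable.
p-distance is the default model, matching the identity statistics; no
substitution-model correction is applied.

## The synthetic generator and its calibration

Each monomer copy mutates independently: every *mutable* column
substitutes with probability `q`, uniformly to one of the 3 alternatives.
Two copies then match at a mutable column with probability
`w(q) = (1−q)² + q²/3`, and at a column where two HOR class consensuses
differ with probability `m(q) = 2q(1−q)/3 + 2q²/9`.  These closed forms
are inverted to map target identities onto rates:

* 43 bp dimeric family: `calibrate_hor(0.89, 0.685)` gives q ≈ 0.0572 and
  a between-class divergence of ≈ 0.24 of columns (10 of 43), applied as
  composition-preserving transversions (A↔T, C↔G) so the two class
  consensuses — and the mosaic family consensus majority-voted from a
  class mixture — keep the calibrated AT content (60.5 %).
* 177 bp family: a uniform per-site model cannot jointly produce ~84 %
  mean pairwise identity and ~53 % of columns monomorphic across 131
  sequences (any such q leaves essentially no column untouched in a
  sample that large).  Real satellite monomers concentrate variation in
  hotspot columns, and the generator emulates that:
  `variable_fraction = 1 − 0.5311` of columns are mutable at
  q ≈ 0.198 (from `calibrate_within_rate(0.839, vf)`), the rest are
  invariant.  Columns of a restriction site with intact fraction < 1 are
  de-facto variable and consume part of the variable budget, keeping the
  conserved fraction exact.

Composition is pinned, not sampled: backbones are drawn with exactly
`round(at_target · L)` A/T bases and nudged back to that count after motif
and site planting (a lone 43-mer would otherwise carry ~7 pp of AT noise).
Planted enzyme sites are made unique by scrubbing chance matches from the
consensus — scanned *circularly*, because the junction between tandem
copies can spell a site that would be exactly as conserved as an internal
one — and per emitted copy, so that site presence is governed by
`intact_fraction` alone.  Motif copies are planted at exactly
`round((1−identity)·length)` substitutions, non-overlapping, with a
packing diagnostic when they cannot fit.

Reads: lengths are truncated-normal (default mean 350, sd 100, min 50),
sources are chosen per read by the per-family abundance targets, the start
is uniform within the source array, either strand, with i.i.d. substitution
errors (default 0.5 %, a post-quality-trim level).  Defaults elsewhere
mirror the study conditions: library sizes 105,277 (male) and 82,143
(female), family abundances 3.93 %/3.38 % (43 bp family) and
3.79 %/3.05 % (177 bp family).  The same seed yields byte-identical
libraries and truth tables.

## Motif scan

The internal-repeat scan is exhaustive over equal-length substring pairs
(Hamming identity; inverted pairs against the reverse complement of the
second copy), vectorized per offset (direct) and per anti-diagonal of the
base-vs-complement match matrix (inverted).  The two copies of a hit must
be disjoint — overlapping pairs are degenerate restatements of local
periodicity or palindromicity.  Greedy reduction ranks by
matches-minus-mismatches, `(2·identity − 1)·length`, with identity
breaking ties, so an exact planted motif outranks noisy extensions of
itself; kept hits may not overlap a better hit's copies by more than half
the shorter interval.  Defaults (min length 8, min identity 0.65) are set
to recover 9 bp exact and 18–23 bp ~67–70 %-identity motifs; direct hits
under 12 bp are additionally flagged as "short repeats".

## Abundance classification

A read is family-positive when one consensus copy matches it as an infix
at ≥ 70 % identity (edit-distance based, either strand) — the one-monomer
span criterion.  The default engine is edlib (C library), which makes
10⁵-read libraries a seconds-scale problem; the package's wraparound-DP
route is available as `engine="wraparound"` and agrees with the fast path
on simulated reads.  The headline statistic is the pooled two-proportion
z-test without continuity correction (z² equals the 2×2 Pearson
chi-square, both reported), with Fisher's exact test substituted when any
expected cell is below 5.  No multiple-testing correction is applied by
default (two families, as analyzed); Bonferroni is a flag away.

## Problem sizes in the shipped analyses

The acceptance script and tests use stand-in monomer sets at the published
set sizes (131 and 232 monomers), 400-read probes for period recovery,
60-copy arrays for ladder prediction, 60-read libraries for monomer
extraction (~500 complete monomers), and 50,000-read libraries per sex for
the abundance comparison — the smallest sizes at which the tested effects
are statistically unambiguous.

## Limitations

* The generator's dimeric HOR is *clean*: classes alternate perfectly and
  divergence is i.i.d. per copy.  Real arrays undergo homogenization
  (unequal crossover, gene conversion) that correlates neighbours and
  admits units belonging to neither class; consequently the stand-in's
  whole-family mean identity (~0.79 for the 43 bp family) and
  non-contiguous fraction (~1.0) sit above the corresponding published
  deposited-data values (0.742 and ~0.6), which are mutually incompatible
  with any clean two-class mixture at 0.89/0.685 within/between identity.
  Passing tests therefore establishes correct *recovery of planted
  structure*, not that real arrays look like the generator's.
* Sequencing errors are i.i.d. substitutions; 454-specific homopolymer
  indel errors are not modelled, and quality trimming is emulated only as
  a constant-quality placeholder.
* Indels within monomers are off by default (monomer sizes in the target
  families vary by ≤ 2 bp); the star MSA and truth-table tiling invariants
  assume the substitution-only default.
* No affine gaps, no amino-acid support, no model-corrected distances
  (K2P and the like) — p-distance is the working convention throughout.
* The gel-estimated ladder unit of a ~177 bp family reads as ~177 bp here;
  reconciling gel-estimated (~200 bp) and sequence-derived unit lengths is
  not attempted — the sequence-derived monomer is treated as truth and the
  ladder unit as an estimate.
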