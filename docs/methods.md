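# Methods

`cobindscan` analyses the co-occupancy of two transcription factors on a
shared set of regulatory regions, the motivating case being a cardiac
homeodomain factor (an NKX2-5-like "selex" motif) and a MEIS-family factor
whose binding site can overlap the first factor's site in a single
composite ("de novo"/hybrid) element.  This note records the models,
conventions, parameters and design choices behind each stage, and what the
synthetic-data validation does and does not establish.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED convention).  A narrowPeak
summit is a 0-based offset from the interval start; column 10 = -1 means
"summit absent", in which case every summit-centric operation falls back to
the interval midpoint `floor((start+end)/2)` — the standard fallback when a
peak caller did not emit summits.  `PeakSet` is sorted and forbids two
fully identical intervals (same coordinates, name, score and summit);
shuffling preserves names, so named inputs cannot collide.  For anonymous
BED3 input a random collision would raise; on realistic genomes this is
astronomically unlikely.

## Motif model and scanning

A PWM is a w x 4 position probability matrix with a background vector b;
a window x_1..x_w scores `sum_i log2(p_i(x_i) / b(x_i))` bits.  PWMs built
from counts use a background-proportional pseudocount
(`probs = (counts + pc*b) / (rowsum + pc)`, default pc = 0.1).  Both
strands are scanned by default (reverse strand = reverse-complemented PWM
on the forward sequence, positions reported in forward coordinates);
windows containing N are never scored.

Score thresholds come from the exact null distribution of the score of a
background-distributed window, computed by positional convolution after
rounding per-position scores to multiples of a granularity g (default 1e-3
bits, configurable).  `threshold_for_pvalue(p)` returns the smallest grid
score whose upper tail is <= p; p = 1 gives the minimum attainable score,
and when even the single best outcome has mass > p the threshold is +inf
(a scan at that threshold reports nothing).  The default scan p-value is
1e-4 per window per strand, the conventional FIMO default.  Because raw
window scores are compared against a rounded-grid threshold, a window can
differ from its rounded score by up to w*g/2 (< 0.005 bits at defaults);
this is the usual discretization trade-off and is negligible against the
bit-scale separation of real matches.

Region classification scans the summit +/- k window (default k = 25, i.e.
a 51-bp window) with both PWMs and assigns exactly one of four exclusive
classes: `both`, `denovo_only`, `selex_only`, `neither`.  The summary
reports marginal fractions ("with de novo" = both + denovo_only) as
percentages at one decimal.

## ZOOPS-EM motif discovery

The de novo discovery stand-in fits a zero-or-one-occurrence-per-sequence
(ZOOPS) mixture by EM: each sequence either has no site (probability
1-gamma) or one site uniform over its offsets.  The E-step computes the
posterior over (no site, each offset) from per-window likelihood ratios;
the M-step re-estimates the PWM from posterior-weighted base counts with
background-proportional pseudocounts and gamma from mean occupancy
(clipped to [1e-3, 1-1e-3] for numerical stability).  Restarts (default 5)
initialize from a randomly chosen sequence window (0.7 on the window base,
0.1 elsewhere).  EM converges readily to a one-base phase shift of the
true motif, so after each restart a shift-refinement step re-runs EM from
the +/-1 column-shifted matrix and keeps any likelihood improvement; the
highest-likelihood PWM over all restarts is returned.  Discovery is
forward-strand only and single-width — deliberately minimal compared with
a full MEME-ChIP workflow (no multiple widths, no dinucleotide background,
no strand symmetrization).

## Co-occupancy statistics

`overlap_partition(A, B)` counts A regions overlapping at least one B
region by >= 1 bp (multi-hits counted once); percentages are rounded
half-up at two decimals, matching the convention of printed study tables.
`summit_overlap` repeats the partition on summit +/- k windows (default
k = 6; two summits are "direct" when they lie within 12 bp, since the
13-bp windows then intersect).  Windows of distinct peaks may coincide, so
the summit partition counts over plain window lists rather than a
distinct-interval container.

The permutation null re-places each A interval uniformly on the genome,
length preserved: a chromosome is chosen with probability proportional to
its number of feasible starts (L_chrom - L + 1) and the start uniformly
among them; placements may overlap each other and the original loci (no
exclusion masks — matching default random-placement semantics of the
standard interval toolkits).  With n_perm permutations (default 10,000)
the fold enrichment is observed / mean(permuted shared count) and the
empirical p-value uses the add-one (Phipson-Smyth) estimator
`(1 + #{perm >= obs}) / (n_perm + 1)`, which cannot be zero.  Per-iteration
RNG streams derive from the master seed by a counter-based SeedSequence
spawn key, so results do not depend on iteration order.  The permutation
statistic is the count of A regions overlapping B (region counts, not
bases), matching the partition semantics.  The permuted-count SD is
reported with ddof = 1.

## Target assignment and integration

Each region is assigned its two nearest genes within 1 Mb, distance
measured summit-to-TSS (|summit - TSS|); ties break lexicographically by
gene id for determinism.  Summit-to-TSS was chosen because every motif
analysis in the workflow is summit-centric; an `edge` mode (gap to the
nearest interval edge, 0 inside) is available as a configuration switch
since either convention is defensible.  The DE filter keeps
|log2FC| >= log2(min_fc) (boundary inclusive, default min_fc = 1.5) and
adjusted p <= max_adj_p (default 0.05).  Direct targets are the
intersection of bound genes with filtered DE calls; genes supported by
several regions count once, with the supporting-region count retained.
Direction is the sign of log2FC.

2x2 contingency analyses use the exact two-sided hypergeometric rule (sum
of fixed-margin tables at most as probable as the observed one — the
standard Fisher convention; the "doubling" alternative is not used), with
odds ratio (a*d)/(b*c) and an infinity sentinel when b*c = 0; a zero margin
yields p = 1 with a warning.  Per-category direction tests
(category vs rest x down vs up) are reported unadjusted with an optional
Benjamini-Hochberg column.

## Synthetic-data generator

The generator's defaults are the package's study conditions, a roughly
tenfold scale-down of a typical embryonic-heart ChIP-seq comparison
(~2,600 regions for the cardiac factor): a 2-Mb genome (4 x 500 kb,
uniform base composition), 261 A peaks vs 600 B peaks of width 200 bp,
shared fraction 0.2931 (shared count = round-half-up(f * n_A) = 76),
summit jitter N(0, 20 bp) on shared pairs (so the summit +/- 6 bp
criterion separates direct from merely proximal pairs), motif-class mix
50/40/5/5 (denovo_only / selex_only / both / neither, apportioned to exact
counts by largest remainder), 400 genes, 9.3% of bound genes planted as
direct targets (the direct-target-to-flanking-gene ratio typical of such
integrations, ~300 of ~3,300),
category mix AVC 0.30 / chamber 0.20 / pan 0.50 with down-regulation bias
0.5 / 0.8 / 0.5 — the chamber-restricted repression signal, giving ~56%
down overall.

Construction guarantees exactness where the pipeline is deterministic:
peaks occupy non-overlapping 800-bp slots (so the shared count is exactly
the planted one); shared A peaks copy their B partner's interval with a
jittered summit; motifs are planted by substring substitution at the
summit (denovo = the hybrid consensus centred on the summit; selex offset
-20 in the `both` class so the two sites do not collide; non-shared B
peaks carry the MEIS consensus).  The hybrid consensus is built by writing
the MEIS consensus `CTGACAG` starting at offset 4 inside the selex
consensus `CAAGTGG`, yielding `CAAGCTGACAG`: its 3' end matches MEIS
exactly while the 5' half resembles the selex site — one composite element
that either factor's model can match but that neither cross-fires on at
the 1e-4 threshold.  Planted targets get adj_p ~ U(0, 0.01) and
|log2FC| ~ U(0.7, 2.5); all other genes get sub-threshold noise
(adj_p ~ U(0.2, 1), |log2FC| < 0.59), so the DE filter recovers the
planted set with zero error.  A fraction (0.35) of unbound genes is also
made significant to populate the DE-only part of the Venn diagram.

Gene TSSs are placed uniformly; on a compact, densely peaked toy genome no
gene can be more than 1 Mb from every peak, so "unbound" cannot be
enforced geometrically.  Instead the generator computes the bound set with
its own exhaustive per-peak scan and plants targets as a subset of it —
the same exact-truth property by a different route.  An `audit` routine
re-reads every emitted file and re-verifies all planted assertions
(substrings at summit-relative coordinates, overlap pair identities, DE
signs and thresholds), failing with named assertions on any tamper.

What passing on synthetic data does not show: real ChIP-seq peaks have
correlated locations, GC-biased and repeat-structured genomes, soft motif
instances and mis-called summits; real DE tables have correlated noise and
no clean threshold separation.  The synthetic results validate the
arithmetic and the statistical machinery, not the biological effect sizes.

## Pipeline

`run_pipeline` executes classify -> overlap -> summit-overlap ->
permutation enrichment -> gene assignment -> DE filter -> direct targets
-> direction fractions -> category analysis, logs one structured line per
stage, and caches each stage's JSON output under a content hash of its
inputs and parameters (re-running with unchanged inputs reuses the cache).
Reports carry no timestamps, so reruns are byte-identical.  All randomness
flows from the single config seed.

## Known limitations

* No GC- or gap-matched shuffling; the permutation null is uniform.
* Single min-overlap fast path (>= 1 bp) in the permutation counter; the
  general intersection supports arbitrary minimum overlaps.
* ZOOPS discovery is forward-strand, single-width, 0-order background.
* Fisher tests are 2x2 only; multi-category tables are analysed as
  category-vs-rest.
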