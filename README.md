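# cobindscan

Co-occupancy and composite binding-site analysis for paired
transcription-factor ChIP-seq peak sets.

During heart development, the homeodomain factors NKX2-5 and MEIS1 can
regulate a common pool of enhancers through a *composite* element: a single
site whose 5' portion resembles the NKX2-5 ("selex") consensus and whose 3'
portion matches the MEIS1 motif, so that binding by the two factors is
mutually exclusive.  Establishing that two factors share enhancers this way
takes a chain of genomic computations: motif occurrence classification
around peak summits, peak-set overlap with a permutation null, summit-level
"direct overlap" criteria, peak-to-gene assignment, and intersection with
differential expression.  `cobindscan` packages that chain as a tested,
reusable pipeline for anyone analysing a pair of ChIP-seq peak sets
(developmental biologists, regulatory genomicists), exercised end-to-end on
synthetic genomes with planted ground truth.

## What it computes

* **Motif occurrence classes.**  Each region's summit ± k window (default
  k = 25 bp) is scanned with two PWMs.  A window scores
  `sum_i log2(p_i(x_i)/b(x_i))` bits; the score threshold is the exact
  p-value cutoff (default p < 1e-4 per window, FIMO-style) computed from
  the full null score distribution by dynamic programming.  Regions fall
  into four exclusive classes: de-novo-only / selex-only / both / neither.
* **Overlap partition and summit criterion.**  The fraction of A regions
  overlapping ≥ 1 B region, plus the same partition restricted to
  summit ± 6 bp windows, separating directly overlapping sites from merely
  proximal ones.
* **Permutation enrichment.**  Fold = observed shared count over the mean
  across n (default 10,000) uniform length-preserving re-placements of A,
  with an add-one empirical p-value: `(1 + #{perm ≥ obs}) / (n + 1)`.
* **Direct targets.**  Two nearest genes within 1 Mb of each summit,
  intersected with a DE table filtered at fold change ≥ 1.5, with
  up/down-regulation fractions and per-category (AVC / chamber /
  pan-myocardial) two-sided Fisher exact tests.
* **De novo motif discovery** (minimal stand-in): ZOOPS EM with seeded
  restarts and phase-shift refinement.
* **Synthetic data.**  A generator that plants motif classes, shared peak
  fractions, summit jitter, and dysregulated target genes with exact
  machine-readable truth, plus a self-audit that re-verifies every planted
  assertion from the emitted files.

## Worked example

Simulate a dataset at the default study conditions (261 vs 600 peaks on a
2-Mb genome, shared fraction 0.2931, 50/40/5/5 motif-class mix, planted
direct targets) and run the full pipeline:

```sh
cobindscan simulate --seed 1 --out demo/sim
cobindscan run-all --config demo/config.yaml   # paths to demo/sim files
```

Key fields of the resulting `demo/out/report.json`:

```json
{
 "overlap":  {"n_a": 261, "n_b": 600, "n_shared_a": 76,
              "n_a_only": 185, "pct_shared_a": 29.12},
 "summit_overlap": {"n_shared_a": 35},
 "n_proximal_not_direct": 41,
 "enrichment": {"observed": 76, "perm_mean": 31.2765,
                "fold": 2.43, "empirical_p": 9.999e-05},
 "motif_classes_summary": {"pct_denovo": 55.2, "pct_selex": 44.8,
                           "pct_both": 5.0, "pct_neither": 5.0},
 "direct_targets": {"n_direct_targets": 26, "n_down": 15, "n_up": 11,
                    "pct_down": 57.7, "pct_up": 42.3}
}
```

Reading: 76 of the 261 A regions (29.12%) overlap a B region — exactly the
planted shared count (round-half-up of 0.2931 × 261).  Only 35 of those
pairs have summits within the ±6 bp direct-overlap criterion; the other 41
are proximal but not directly overlapping.  The shared count is 2.4-fold
above the permutation mean (31.3) and no permutation reached it
(p ≈ 1e-4, the add-one floor at 10,000 permutations).  Motif classes
recover the planted 50/40/5/5 mix within sampling noise (the de novo
fraction 55.2% counts both-class regions too), and the 26 direct targets
are exactly the planted set, 57.7% of them down-regulated.

Every subcommand (`classify`, `overlap`, `summit-overlap`, `enrich`,
`targets`, `integrate`, `categories`) runs its stage standalone on
BED/narrowPeak, FASTA, MEME-minimal, and TSV inputs; the same operations
are importable from `cobindscan` as a library.

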