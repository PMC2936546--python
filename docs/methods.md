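# Methods

`hsescan` models the analysis of an inducibly activated, sequence-specific
transcription factor (heat-shock factor, HSF) profiled by ChIP-seq, with an
RNAi knockdown of the factor as the specificity control and tiling-array
chromatin tracks as the context readout. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not establish.

## The analysis model

**Tags and normalization.** A tag is the uniquely aligned 5′ end of one
sequenced ChIP fragment: (chromosome, position, strand). All intensities are
normalized tag counts — raw 5′-end counts in a window scaled by 10⁷ / (aligned
tags in the library) — so libraries of different depth are comparable. The
normalization denominator is the *aligned*-tag total, because densities are
computed from mapped tags. Density tracks shift plus-strand tags by +s and
minus-strand tags by −s (fragment-center correction) before binning into
10-bp bins.

**Knockdown-sensitivity filter.** Candidate peaks come from two callers at
different granularity: a point caller (summits) and a region caller
(boundaries). Calls agree when the point caller's center falls inside the
region caller's boundary; agreed pairs merge (center from the point caller,
boundary from the region caller) and caller-unique peaks are retained as
candidates. Each candidate's depletion is

    depletion = window_count(exp, center, 240) / window_count(kd, center, 240)

and a peak is *sensitive* (kept) when either

1. it is also called in the knockdown data and its depletion exceeds the
   depletion observed at a high-affinity reference locus (the study's
   reference promoter retained under 70 % of its signal, so the default
   reference ratio is 1/0.7 ≈ 1.43), or
2. it is absent from the knockdown calls and depleted at least 3-fold;

otherwise it is *resistant* and discarded as a false positive. Depletion is
defined as exp/KD (> 1 = depleted), which makes both criteria one-sided;
"called in the knockdown data" means ≥ 1 base of boundary overlap; a zero
knockdown count adds one normalized unit to numerator and denominator
(preserves ordering, avoids infinities). Peaks are never re-centered after
classification.

**Motif model.** The HSE is a tandem array of three oppositely oriented
5-bp AGAAN-type units; the degenerate seed is `NTTCNNGAANNTTCN` (width 15).
Instead of EM-based discovery, a deterministic seed-consensus extractor scans
the 120-base window on each sensitive peak center (the ±60-base flanks) with
the seed on both strands, keeps the best oriented occurrence per window,
builds a matrix (pseudocount 0.25 total mass, 0-order background), and
refines once by rescanning with the built matrix. Log-odds scores are in
bits. **Scores are quantized to the lattice step `score_granularity`
(10⁻³ bits) when the matrix is built**, so the scanner and the
dynamic-programming p-value share one score space: `score_pvalue` convolves
the per-position lattice score distributions under the background model and
is therefore exact (to float summation error) for every score the scanner can
produce. Zero-probability cells and N bases score −∞; their probability mass
is tracked separately so p-values stay exact. Opposite-strand hits whose
footprints overlap ≥ 50 % collapse to the better score; exact ties keep the
lexicographically smaller oriented sequence — a reverse-complement-invariant
choice — then the plus strand.

**Thresholds.** Bound-motif screen at p < 10⁻³ (assignment of the nearest
motif within 60 bases of each sensitive peak center); free-motif screen at
p ≤ 5×10⁻⁶. Free motifs additionally require a fully mappable 400-base
flanking window — every 40-mer start inside the window unique in the genome,
counting forward and reverse-complement occurrences jointly, because a
sequenced tag can come from either strand — and no overlap with any sensitive
peak. Mappability is exact hash-based counting (no mismatch tolerance);
windows clipped at a chromosome edge are conservatively non-mappable.

**Annotation.** Promoters are the 500 bases immediately upstream of a TSS,
strand-aware, *not* clipped by neighbouring gene bodies; a coordinate can be
both genic and promoter, so class fractions may exceed 1. Genome composition
is base-pair union coverage. Motifs are classified by their center, against
every annotated TSS.

**Landscape.** Composite profiles average track intensity in 100-base
windows stepped by 50 over ±2000 bases around motifs, strand-flipped to
motif orientation, each motif weighted equally regardless of probe count;
probe-free windows drop out of that offset's mean with the count reported.
Association per factor is the two-sided Fisher exact test on the 2×2 table
(bound/free × center inside/outside an enriched region); two-sided is the
conservative default (one-sided available), no correction across factors is
applied to the primary p-value but a Benjamini–Hochberg column is emitted.
Odds ratios use the Haldane–Anscombe +0.5 correction when a cell is zero.
Clustering is k-means (k = 5) on per-factor z-scored 400-base mean probe
intensities, missing values imputed with the column mean, best of 10 seeded
restarts; rows are presented to the solver in canonical order and clusters
relabelled by centroid norm, making the result invariant to motif input
order under a fixed seed.

## Synthetic data

The generator emulates the study design with exact bookkeeping
(`SyntheticTruth`): a uniform-composition random genome; planted bound- and
free-class HSEs sampled from a sharp consensus matrix (match probability
0.94 at the nine informative positions); direct-repeat AGAAN decoys that a
correct scanner must not call; one true knockdown-sensitive peak centered on
each bound motif; knockdown-resistant false-positive peaks at motif-free
positions; five tag libraries (experimental and knockdown under non-heat-shock
and heat-shock conditions, plus pre-immune background); and probe-level
chromatin tracks whose 500-base enriched blocks co-occur with bound vs free
motifs at configurable class probabilities.

Defaults are the study conditions: 40× peak enrichment, 40× knockdown
depletion (the measured depletion of the factor), inducible binding absent
in non-heat-shock libraries, knockdown-resistant peaks at full enrichment in
every IP library, association probabilities 0.7 (bound) vs 0.1 (free). The
per-base background rate (0.05 tags/base) gives ~12 background tags per
240-base window, deep enough that a 40× peak is unambiguous — comparable, per
window, to a saturated fly-genome library. Signal tags place their 5′ ends at
center ± d with d ~ Normal(75, 20) bases on opposite strands; the
displacement is a free parameter (no fragment-length estimate is published
for the study data), chosen so the strand-asymmetric shift machinery is
genuinely exercised. Planted motif instances are resampled until they meet
the strictest scan threshold in use (p ≤ 5×10⁻⁶), so the planted truth is
recoverable by construction — recovery tests measure the pipeline, not the
sampler's tail behaviour. Gene models are alternating blocks covering
roughly 60 % of the genome, matching the annotated fraction of a compact
metazoan genome.

What the generator does *not* emulate: sequencing error, mappability bias,
copy-number structure, non-uniform background (chromatin-accessibility bias),
correlated probe noise, or overlapping genes. Passing recovery tests
therefore show the estimators are correct under the stated model, not that
the pipeline is robust to every artifact of real libraries; on real data the
external caller outputs and mappability tracks enter through the same
interfaces.

## Numerical and design choices

- Coordinates are 0-based, half-open everywhere; a tag BED record is a
  1-base interval, so the 5′ end is `start` on +, `end − 1` on −.
- Even-width windows place the center at the left of the middle pair:
  `[center − w/2, center + w/2)`.
- The internal sliding-window Poisson caller (plumbing; production input is
  external caller output) tests window counts against the background library
  scaled by depth, floored at the background's genome-wide rate,
  BH-adjusted at FDR 0.05; merged significant windows take their summit from
  the maximum-count 10-bp bin of shifted tags. Synthetic runs use it at two
  window widths (150/300) to exercise the point/region reconciliation rule.
- Equidistant motif assignment ties break by higher score, then lower
  coordinate.
- The reference depletion can be given as a ratio, or inferred from the
  strongest candidate peak (mirroring the use of the highest-affinity locus),
  computed per condition.
- k-means is run on data sorted into canonical row order; this trades a
  vanishing amount of speed for order invariance.
- All generators and the pipeline are pure functions of (parameters, seed);
  `run-all` twice with one config and seed is byte-identical.

## Problem sizes

The shipped analysis and tests run on genomes of 120–400 kb with 50–400
planted sites, 10 replicate seeds for filter-recovery rates and 100 seeded
replicates for association power/calibration — sizes at which every
acceptance property is measured with comfortable Monte-Carlo margins while
the whole suite stays fast. All thresholds above are configuration defaults,
not tuned values.

## Known limitations

- Exact-match mappability only; the study's aligner tolerated mismatches, so
  real free-motif sets are slightly conservative here (documented divergence).
- The seed-consensus extractor assumes the seed family is approximately
  right; it cannot discover an unrelated motif the way EM discovery can.
- The internal Poisson caller is deliberately simple (no local lambda
  model, no duplicate handling); it exists so synthetic runs need no
  external caller, not as a general-purpose caller.
- Exact p-value equivalence with any specific external scanner's reported
  values is not guaranteed: p-values depend on the background model and
  score discretization, which differ between tools.
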