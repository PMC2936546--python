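# hsescan

Knockdown-controlled ChIP-seq analysis of inducible transcription-factor
binding at heat-shock elements (HSEs).

## The problem

ChIP-seq of a sequence-specific factor mixes genuine binding events with
false-positive peaks from antiserum cross-reactivity and other artifacts. When
the factor can be RNAi-depleted, a parallel ChIP-seq in knockdown cells gives
a direct specificity control: real peaks collapse under depletion, artifacts
do not. For an inducibly activated factor like heat-shock factor (HSF) —
which trimerizes on heat shock and binds a tandem inverted array of three
AGAAN-type 5-bp units — the validated peak set then anchors a second
question: the genome contains far more strong HSE motifs than the factor
ever binds, so what distinguishes the *bound* motifs from the equally strong,
uniquely mappable but *free* ones? The answer in this framework is the
pre-existing chromatin landscape, read from probe-level tracks (tiling-array
style) around the two motif classes.

`hsescan` implements that whole analysis as a tested, seedable pipeline:

- **`synthetic`** — genomes with planted bound/free/decoy HSEs, five tag
  libraries (experimental/knockdown × NHS/HS + pre-immune) with Poisson
  background and a configurable knockdown depletion (default 40×), and
  chromatin tracks with class-dependent enrichment; exact ground truth.
- **`tag_io`** — tag libraries, normalized window counts
  (counts × 10⁷/library total), shifted 10-bp density tracks, replicate
  correlation.
- **`peak_filter`** — point/region caller reconciliation, the two-criterion
  knockdown-sensitivity classification (reference-locus depletion, 3-fold
  rule, 240-base windows), Ex/KD ratio distributions vs a random null.
- **`motif`** — PSWM construction and seeded discovery, log-odds scoring in
  bits, *exact* p-values by dynamic programming on a shared score lattice,
  genome scanning, nearest-motif assignment to peaks.
- **`mappability`** — exact strand-joint 40-mer uniqueness, fully mappable
  400-base windows, the free-motif definition.
- **`annotation`** — promoter (500 bp upstream of TSS, overlapping classes
  allowed) / genic / intergenic classification and genome composition.
- **`landscape`** — motif-centered composite profiles (100-base windows,
  step 50), Fisher exact bound-vs-free association per factor, k-means
  clustering of 400-base mean intensities, intensity–binding correlations,
  p-value-quartile binding intensities.
- **`pipeline` / `cli`** — one-config orchestration with bit-identical
  reruns under a fixed seed.

## Worked example

The numbered drivers under `analysis/` run the full study design on a
synthetic 400-kb genome (100 bound + 100 free HSEs, 50 direct-repeat decoys,
50 knockdown-resistant false-positive peaks, 40× enrichment and 40×
knockdown depletion) and write their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_filter_peaks.py
python analysis/03_motif_model.py
python analysis/04_free_motifs.py
python analysis/05_chromatin_landscape.py
```

Output from a run with the default seed:

```
caller A: 150 regions; caller B: 150 points; reconciled candidates: 150
knockdown-sensitive: 100 (0 criterion 1, 100 criterion 2); resistant: 50
median Ex/KD at sensitive peaks: 9.8; fraction below the random null's 95th percentile: 0.03
...
100/100 sensitive peaks have a motif within 60 bases
motif within 20 bases of the peak center: 100%; within 60: 100%
...
106 free motifs at p <= 5e-06 (bound set: 100)
...
H3K9ac: bound 68/100 vs free 5/106 enriched, OR=43, p=2.3e-23
H3K9ac composite at the motif: bound 3.03 vs free 1.13
k-means (5 clusters) sizes: [35, 17, 15, 22, 11]
```

Reading this: all 100 planted true peaks survive the knockdown filter while
all 50 knockdown-resistant decoys are discarded (here every sensitive peak
passed via the 3-fold criterion because the 40×-depleted knockdown signal
fell below the caller's threshold); every sensitive peak has its motif
within 20 bases of the summit; the free set is the 100 planted free HSEs plus
a handful of chance matches in 400 kb of random sequence; and the planted
0.7-vs-0.1 association of chromatin marks with the bound class is recovered
with odds ratios ≫ 1 and tiny Fisher p-values. The composite at the motif
(3.03 vs baseline ≈ 1) matches the expectation 0.7 × 4 + 0.3 × 1 ≈ 3.1 for
4-fold blocks present at 70 % of bound motifs.

The same run is available as one command:

```sh
hsescan run-all --seed 1 --out-dir results/run
```

and the stage-level subcommands (`simulate`, `filter-peaks`, `scan`,
`free-motifs`, `annotate`, `profile`, `associate`, `cluster`) operate on
FASTA/BED/bedGraph files so external caller output or real tracks can replace
any simulated stage.

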