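#!/usr/bin/env python
"""Build the HSE matrix from the 60-base flanks of sensitive peak centers,
scan the genome at the bound-motif threshold (p < 0.001), and assign each
sensitive peak its nearest motif.

Reads results/data/ and results/peaks_classified.bed; writes
results/motif.meme, results/motifs_bound.bed, results/motif_distances.tsv.
"""

import os

import numpy as np

from hsescan import motif, peak_filter, pipeline, synthetic
from hsescan.pipeline import PipelineConfig

DATA = os.path.join("results", "data")


def main() -> None:
    cfg = PipelineConfig(seed=1)
    genome = synthetic.read_fasta(f"{DATA}/genome.fa")
    chrom, seq = next(iter(genome.items()))
    classified = peak_filter.read_peaks_bed("results/peaks_classified.bed")
    sensitive = [p for p in classified if p.is_sensitive]

    flanks = [seq[max(0, p.center - 60) : p.center + 60] for p in sensitive]
    pswm = motif.discover_pswm(flanks)
    motif.write_meme(pswm, "results/motif.meme")

    hits = motif.scan_genome(genome, pswm, p_threshold=cfg.bound_p)
    rng = np.random.default_rng(cfg.seed)
    assignments, distances, random_distances = motif.assign_peak_motifs(
        sensitive, hits, p_threshold=cfg.bound_p, search_halfwidth=60,
        rng=rng, genome_length=len(seq),
    )
    bound = sorted(
        {id(h): h for h in assignments.values() if h is not None}.values(),
        key=lambda h: h.start,
    )
    with open("results/motifs_bound.bed", "w") as fh:
        for h in bound:
            fh.write(pipeline._format_hit(h))
    with open("results/motif_distances.tsv", "w") as fh:
        fh.write("set\tdistance\n")
        for d in distances:
            fh.write(f"peaks\t{d}\n")
        for d in random_distances:
            fh.write(f"random\t{d}\n")

    n_with = sum(h is not None for h in assignments.values())
    w20 = float(np.mean(np.abs(distances) <= 20)) if len(distances) else 0.0
    w60 = float(np.mean(np.abs(distances) <= 60)) if len(distances) else 0.0
    print(f"matrix: width {pswm.width}, consensus {pswm.consensus()}")
    print(f"{len(hits)} genome-wide hits at p <= {cfg.bound_p}")
    print(f"{n_with}/{len(sensitive)} sensitive peaks have a motif within 60 bases")
    print(f"motif within 20 bases of the peak center: {100 * w20:.0f}%; within 60: {100 * w60:.0f}%")
    print(f"median |random-coordinate distance|: {np.median(np.abs(random_distances)):.0f} bases")


if __name__ == "__main__":
    main()
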