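#!/usr/bin/env python
"""Define the factor-free motif set: rescan at the conservative threshold
(p <= 5e-6), keep motifs whose 400-base flank is fully mappable for 40-mer
tags and which overlap no knockdown-sensitive peak, then compare the
annotation-class composition of bound vs free motifs and of the genome.

Reads results/data/, results/peaks_classified.bed, results/motif.meme and
results/motifs_bound.bed; writes results/motifs_free.bed and
results/annotation_composition.tsv.
"""

import os

from hsescan import annotation, mappability, motif, peak_filter, pipeline, synthetic
from hsescan.pipeline import PipelineConfig

DATA = os.path.join("results", "data")


def main() -> None:
    cfg = PipelineConfig(seed=1)
    genome = synthetic.read_fasta(f"{DATA}/genome.fa")
    chrom, seq = next(iter(genome.items()))
    pswm = motif.read_meme("results/motif.meme")
    classified = peak_filter.read_peaks_bed("results/peaks_classified.bed")
    sensitive = [p for p in classified if p.is_sensitive]

    hits = motif.scan_genome(genome, pswm, p_threshold=cfg.bound_p)
    assignments, _, _ = motif.assign_peak_motifs(
        sensitive, hits, p_threshold=cfg.bound_p, search_halfwidth=60
    )
    bound = sorted(
        {id(h): h for h in assignments.values() if h is not None}.values(),
        key=lambda h: h.start,
    )
    track = mappability.kmer_uniqueness(genome, k=cfg.mappability_k)
    free = mappability.find_free_motifs(
        hits, assignments, track, p_threshold=cfg.free_p, window=cfg.mappability_window
    )
    with open("results/motifs_free.bed", "w") as fh:
        for h in free:
            fh.write(pipeline._format_hit(h))

    genes = annotation.read_genes_bed(f"{DATA}/genes.bed")
    comp_bound = annotation.class_composition(bound, genes, cfg.promoter_size)
    comp_free = annotation.class_composition(free, genes, cfg.promoter_size)
    comp_genome = annotation.genome_composition(genes, len(seq), cfg.promoter_size)
    with open("results/annotation_composition.tsv", "w") as fh:
        fh.write("set\tclass\tcount\tfraction\n")
        for name, comp in (("bound", comp_bound), ("free", comp_free)):
            for cls, d in comp.items():
                fh.write(f"{name}\t{cls}\t{d['count']}\t{d['fraction']:.4f}\n")
        fh.write(f"genome\tgenic\t-\t{comp_genome['genic_fraction']:.4f}\n")
        fh.write(f"genome\tpromoter\t-\t{comp_genome['promoter_fraction']:.4f}\n")

    n_unique = int(sum(t.sum() for t in track.unique.values()))
    n_total = sum(len(t) for t in track.unique.values())
    print(f"mappability: {100 * n_unique / n_total:.2f}% of 40-mer starts unique")
    print(f"{len(free)} free motifs at p <= {cfg.free_p} (bound set: {len(bound)})")
    print(
        f"bound motifs: {100 * comp_bound['genic']['fraction']:.0f}% genic, "
        f"{100 * comp_bound['promoter']['fraction']:.0f}% promoter; "
        f"free motifs: {100 * comp_free['genic']['fraction']:.0f}% genic, "
        f"{100 * comp_free['promoter']['fraction']:.0f}% promoter"
    )
    print(
        f"genome: {100 * comp_genome['genic_fraction']:.1f}% genic, "
        f"{100 * comp_genome['promoter_fraction']:.1f}% promoter"
    )


if __name__ == "__main__":
    main()
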