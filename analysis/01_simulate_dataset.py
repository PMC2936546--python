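#!/usr/bin/env python
"""Generate the synthetic study dataset: genome with planted HSE motifs,
five tag libraries (experimental/knockdown x NHS/HS + pre-immune), and
chromatin tracks whose enrichment co-occurs with the bound motif class.

Writes FASTA/BED/bedGraph/JSON ground truth under results/data/.
"""

import json
import os

from hsescan import annotation, landscape, synthetic, tag_io
from hsescan.pipeline import PipelineConfig

OUT = os.path.join("results", "data")


def main() -> None:
    cfg = PipelineConfig(seed=1)
    os.makedirs(OUT, exist_ok=True)

    genome, truth = synthetic.generate_genome(
        length=cfg.genome_length, n_bound=cfg.n_bound, n_free=cfg.n_free,
        n_decoy=cfg.n_decoy, n_kd_resistant=cfg.n_kd_resistant,
        min_spacing=cfg.min_spacing, enrichment_fold=cfg.enrichment_fold,
        seed=cfg.seed, plant_max_p=cfg.free_p,
    )
    libs = synthetic.simulate_tag_libraries(
        truth, background_rate=cfg.background_rate, kd_depletion=cfg.kd_depletion,
        fragment_sd=cfg.fragment_sd, shift_mean=cfg.shift_mean,
        signal_window=cfg.filter_window, seed=cfg.seed + 1,
    )
    tracks = synthetic.simulate_chromatin_tracks(
        truth, probe_spacing=cfg.probe_spacing, assoc_prob_bound=cfg.assoc_prob_bound,
        assoc_prob_free=cfg.assoc_prob_free,
        signal_fold={f: cfg.signal_fold for f in cfg.factors},
        noise_sd=cfg.noise_sd, seed=cfg.seed + 2,
    )

    synthetic.write_fasta({truth.chromosome: genome}, f"{OUT}/genome.fa")
    synthetic.write_truth(truth, f"{OUT}/truth.json", f"{OUT}/truth_motifs.tsv")
    annotation.write_genes_bed12(truth.gene_models, f"{OUT}/genes.bed")
    for lib_id, lib in libs.items():
        tag_io.write_tags_bed(lib, f"{OUT}/tags_{lib_id}.bed")
    for factor, track in tracks.items():
        landscape.write_track_bedgraph(
            track, f"{OUT}/track_{factor}.bedgraph", f"{OUT}/track_{factor}_enriched.bed"
        )
    with open(f"{OUT}/config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    print(f"genome: {truth.genome_length} bases, {len(truth.gene_models)} gene models")
    print(
        f"planted: {cfg.n_bound} bound + {cfg.n_free} free HSEs, {cfg.n_decoy} "
        f"direct-repeat decoys, {cfg.n_kd_resistant} knockdown-resistant false peaks"
    )
    for lib_id, lib in libs.items():
        print(f"library {lib_id}: {lib.n_tags} tags")


if __name__ == "__main__":
    main()
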