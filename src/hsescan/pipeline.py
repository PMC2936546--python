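"""End-to-end orchestration: simulate -> call -> reconcile -> filter -> motif ->
mappability -> annotate -> landscape, with one config and reproducible seeds.

Every threshold default is the value the analysis is defined with: bound-motif
p < 0.001, free-motif p <= 5e-6, 240-base filter window, 3-fold knockdown
depletion, 500-bp promoters, 40-mer mappability in 400-bp windows, 100/50
composite windows, 400-base intensity windows, five clusters.  A bare
synthetic run therefore mirrors the full published procedure on generated
data, and rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from hsescan import __version__, annotation, landscape, mappability, motif, peak_filter
from hsescan import synthetic, tag_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs for a synthetic end-to-end run (file-based inputs may
    substitute any simulated stage through the CLI subcommands)."""

    out_dir: str = "results/run"
    seed: int = 0

    # synthetic genome
    genome_length: int = 400_000
    n_bound: int = 100
    n_free: int = 100
    n_decoy: int = 50
    n_kd_resistant: int = 50
    min_spacing: int = 600
    enrichment_fold: float = 40.0

    # tag simulation
    background_rate: float = 0.05
    kd_depletion: float = 40.0
    fragment_sd: float = 20.0
    shift_mean: float = 75.0

    # chromatin simulation
    factors: tuple = ("H3K9ac", "H4ac", "PolII")
    assoc_prob_bound: float = 0.7
    assoc_prob_free: float = 0.1
    signal_fold: float = 4.0
    noise_sd: float = 0.2
    probe_spacing: int = 36

    # analysis thresholds (the study's values)
    bound_p: float = 1e-3
    free_p: float = 5e-6
    filter_window: int = 240
    min_fold: float = 3.0
    promoter_size: int = 500
    mappability_k: int = 40
    mappability_window: int = 400
    composite_window: int = 100
    composite_step: int = 50
    composite_span: int = 2000
    intensity_window: int = 400
    clusters_k: int = 5
    reference_depletion: float | None = peak_filter.DEFAULT_REFERENCE_DEPLETION

    # internal caller settings (plumbing; external peak calls replace these)
    caller_fdr: float = 0.05
    point_caller_window: int = 150
    region_caller_window: int = 300

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        if "factors" in data:
            cfg.factors = tuple(data["factors"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factors"] = list(self.factors)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations; empty iff the config is usable."""
    v: list[str] = []

    def positive(name: str) -> None:
        if getattr(config, name) <= 0:
            v.append(f"{name}: must be positive")

    for name in (
        "genome_length",
        "filter_window",
        "promoter_size",
        "mappability_k",
        "mappability_window",
        "composite_window",
        "composite_step",
        "intensity_window",
        "clusters_k",
        "min_spacing",
        "probe_spacing",
        "background_rate",
    ):
        positive(name)
    for name in ("bound_p", "free_p", "caller_fdr"):
        val = getattr(config, name)
        if not (0.0 < val <= 1.0):
            v.append(f"{name}: must lie in (0,1]")
    if config.min_fold < 1:
        v.append("min_fold: must be >= 1")
    if config.kd_depletion < 1:
        v.append("kd_depletion: must be >= 1")
    if config.enrichment_fold < 1:
        v.append("enrichment_fold: must be >= 1")
    if config.reference_depletion is not None and config.reference_depletion < 1:
        v.append("reference_depletion: must be >= 1 (or null to infer)")
    if config.mappability_window < config.mappability_k:
        v.append("mappability_window: must be >= mappability_k")
    if config.composite_window < config.composite_step:
        v.append("composite_window: must be >= composite_step")
    for name in ("assoc_prob_bound", "assoc_prob_free"):
        val = getattr(config, name)
        if not (0.0 <= val <= 1.0):
            v.append(f"{name}: must lie in [0,1]")
    for name in ("n_bound", "n_free", "n_decoy", "n_kd_resistant"):
        if getattr(config, name) < 0:
            v.append(f"{name}: must be >= 0")
    return v


# ----------------------------------------------------------------------
def run_all(config: PipelineConfig, write_outputs: bool = True) -> dict[str, Any]:
    """Execute the full synthetic pipeline; returns the run report dict.

    Stages: simulate genome/tags/tracks -> call peaks with the internal
    caller at two granularities and reconcile them -> classify knockdown
    sensitivity -> discover the motif matrix from sensitive-peak flanks ->
    scan the genome -> assign motifs to peaks -> compute mappability and the
    free-motif set -> annotate -> profile and associate chromatin tracks ->
    cluster bound-motif intensities.  All randomness derives from
    ``config.seed``; outputs are plain text and bit-identical across reruns.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = config.out_dir
    if write_outputs:
        os.makedirs(out, exist_ok=True)

    # --- stage 1: synthetic data -------------------------------------
    genome, truth = synthetic.generate_genome(
        length=config.genome_length,
        n_bound=config.n_bound,
        n_free=config.n_free,
        n_decoy=config.n_decoy,
        n_kd_resistant=config.n_kd_resistant,
        min_spacing=config.min_spacing,
        enrichment_fold=config.enrichment_fold,
        seed=config.seed,
        # planted sites always satisfy the strictest screen in use, so truth
        # stays recoverable when free_p is loosened
        plant_max_p=min(config.free_p, 5e-6),
    )
    libs = synthetic.simulate_tag_libraries(
        truth,
        background_rate=config.background_rate,
        kd_depletion=config.kd_depletion,
        fragment_sd=config.fragment_sd,
        shift_mean=config.shift_mean,
        signal_window=config.filter_window,
        seed=config.seed + 1,
    )
    tracks = synthetic.simulate_chromatin_tracks(
        truth,
        probe_spacing=config.probe_spacing,
        assoc_prob_bound=config.assoc_prob_bound,
        assoc_prob_free=config.assoc_prob_free,
        signal_fold={f: config.signal_fold for f in config.factors},
        noise_sd=config.noise_sd,
        seed=config.seed + 2,
    )
    logger.info("simulated %d planted motifs, %d peaks", len(truth.planted_motifs), len(truth.true_peaks))

    # --- stage 2: peak calling + reconciliation ----------------------
    shift = int(config.shift_mean)
    common = dict(
        background=libs["preimmune"],
        fdr_cutoff=config.caller_fdr,
        genome_length=config.genome_length,
        shift=shift,
    )
    peaks_region = peak_filter.call_windows_poisson(
        libs["exp_hs"], window=config.region_caller_window, caller="caller_A", **common
    )
    peaks_point = peak_filter.call_windows_poisson(
        libs["exp_hs"], window=config.point_caller_window, caller="caller_B", **common
    )
    candidates = peak_filter.reconcile_callers(peaks_region, peaks_point)
    kd_peaks = peak_filter.call_windows_poisson(
        libs["kd_hs"], window=config.region_caller_window, caller="caller_A", **common
    )

    # --- stage 3: knockdown-sensitivity filter -----------------------
    classified = peak_filter.classify_rnai_sensitivity(
        candidates,
        kd_peaks,
        libs["exp_hs"],
        libs["kd_hs"],
        reference_depletion=config.reference_depletion,
        window=config.filter_window,
        min_fold=config.min_fold,
    )
    sensitive = [p for p in classified if p.is_sensitive]
    resistant = [p for p in classified if not p.is_sensitive]

    # --- stage 4: motif model + scan + assignment --------------------
    flanks = [
        genome[max(0, p.center - 60) : p.center + 60] for p in sensitive
    ]
    pswm = motif.discover_pswm(flanks) if flanks else synthetic.default_motif_model()
    hits = motif.scan_genome({truth.chromosome: genome}, pswm, p_threshold=config.bound_p)
    rng_assign = np.random.default_rng(config.seed + 3)
    assignments, distances, random_distances = motif.assign_peak_motifs(
        sensitive,
        hits,
        p_threshold=config.bound_p,
        search_halfwidth=60,
        rng=rng_assign,
        genome_length=config.genome_length,
    )
    bound_motifs = sorted(
        {id(h): h for h in assignments.values() if h is not None}.values(),
        key=lambda h: (h.chromosome, h.start),
    )

    # --- stage 5: mappability + free motifs --------------------------
    track_map = mappability.kmer_uniqueness({truth.chromosome: genome}, k=config.mappability_k)
    free_motifs = mappability.find_free_motifs(
        hits,
        assignments,
        track_map,
        p_threshold=config.free_p,
        window=config.mappability_window,
    )

    # --- stage 6: annotation -----------------------------------------
    comp_bound = (
        annotation.class_composition(bound_motifs, truth.gene_models, config.promoter_size)
        if bound_motifs
        else {}
    )
    comp_free = (
        annotation.class_composition(free_motifs, truth.gene_models, config.promoter_size)
        if free_motifs
        else {}
    )
    comp_genome = annotation.genome_composition(
        truth.gene_models, config.genome_length, config.promoter_size
    )

    # --- stage 7: chromatin landscape --------------------------------
    associations = landscape.associate_factors(tracks, bound_motifs, free_motifs)
    profiles = {
        f: {
            "bound": landscape.composite_profile(
                tracks[f], bound_motifs, config.composite_span,
                config.composite_window, config.composite_step,
            ),
            "free": landscape.composite_profile(
                tracks[f], free_motifs, config.composite_span,
                config.composite_window, config.composite_step,
            ),
        }
        for f in sorted(tracks)
        if bound_motifs and free_motifs
    }
    cluster_labels = None
    if len(bound_motifs) >= config.clusters_k:
        mat, factor_names = landscape.intensity_matrix(
            tracks, bound_motifs, config.intensity_window
        )
        cluster_labels, _ = landscape.cluster_motifs(
            mat, k=config.clusters_k, seed=config.seed
        )

    # --- report -------------------------------------------------------
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "planted_bound": len(truth.motifs_of_class("bound")),
            "planted_free": len(truth.motifs_of_class("free")),
            "planted_decoy": len(truth.motifs_of_class("decoy")),
            "true_peaks": sum(1 for p in truth.true_peaks if not p.kd_resistant),
            "kd_resistant_peaks": sum(1 for p in truth.true_peaks if p.kd_resistant),
            "candidate_peaks": len(classified),
            "sensitive_peaks": len(sensitive),
            "resistant_peaks": len(resistant),
            "motif_bearing_peaks": sum(1 for h in assignments.values() if h is not None),
            "bound_motifs": len(bound_motifs),
            "free_motifs": len(free_motifs),
        },
        "genome_composition": comp_genome,
        "class_composition_bound": comp_bound,
        "class_composition_free": comp_free,
        "associations": associations,
        "motif_peak_distances": {
            "median_abs": float(np.median(np.abs(distances))) if len(distances) else None,
            "within_20": float(np.mean(np.abs(distances) <= 20)) if len(distances) else None,
            "within_60": float(np.mean(np.abs(distances) <= 60)) if len(distances) else None,
        },
    }
    counts = report["counts"]
    assert counts["sensitive_peaks"] + counts["resistant_peaks"] == counts["candidate_peaks"]
    free_ids = {id(h) for h in free_motifs}
    assert not free_ids & {id(h) for h in bound_motifs}, "bound and free sets overlap"

    if write_outputs:
        _write_outputs(
            out, config, genome, truth, libs, tracks, classified, pswm, hits,
            bound_motifs, free_motifs, associations, profiles, cluster_labels, report,
        )
    return report


def _format_hit(h: motif.MotifHit) -> str:
    logp = min(999.0, -np.log10(h.p_value)) if h.p_value > 0 else 999.0
    return f"{h.chromosome}\t{h.start}\t{h.end}\t{h.sequence}\t{logp:.3f}\t{h.strand}\n"


def _write_outputs(
    out, config, genome, truth, libs, tracks, classified, pswm, hits,
    bound_motifs, free_motifs, associations, profiles, cluster_labels, report,
) -> None:
    synthetic.write_fasta({truth.chromosome: genome}, os.path.join(out, "genome.fa"))
    synthetic.write_truth(
        truth, os.path.join(out, "truth.json"), os.path.join(out, "truth_motifs.tsv")
    )
    annotation.write_genes_bed12(truth.gene_models, os.path.join(out, "genes.bed"))
    for lib_id, lib in libs.items():
        tag_io.write_tags_bed(lib, os.path.join(out, f"tags_{lib_id}.bed"))
    for factor, track in tracks.items():
        landscape.write_track_bedgraph(
            track,
            os.path.join(out, f"track_{factor}.bedgraph"),
            os.path.join(out, f"track_{factor}_enriched.bed"),
        )
    peak_filter.write_peaks_bed(classified, os.path.join(out, "peaks_classified.bed"))
    motif.write_meme(pswm, os.path.join(out, "motif.meme"))
    with open(os.path.join(out, "motifs_bound.bed"), "w") as fh:
        for h in bound_motifs:
            fh.write(_format_hit(h))
    with open(os.path.join(out, "motifs_free.bed"), "w") as fh:
        for h in free_motifs:
            fh.write(_format_hit(h))
    with open(os.path.join(out, "associations.tsv"), "w") as fh:
        fh.write(
            "factor\tbound_enriched\tbound_total\tfree_enriched\tfree_total\t"
            "odds_ratio\tp_value\tp_adjusted_bh\n"
        )
        for a in associations:
            fh.write(
                f"{a['factor']}\t{a['bound_enriched']}\t{a['bound_total']}\t"
                f"{a['free_enriched']}\t{a['free_total']}\t{a['odds_ratio']:.6g}\t"
                f"{a['p_value']:.6g}\t{a['p_adjusted_bh']:.6g}\n"
            )
    with open(os.path.join(out, "profiles.tsv"), "w") as fh:
        fh.write("factor\tmotif_class\toffset\tmean_intensity\tn_motifs\n")
        for factor in sorted(profiles):
            for cls in ("bound", "free"):
                prof = profiles[factor][cls]
                for off, mean, n in zip(prof.offsets, prof.mean_intensity, prof.n_motifs):
                    val = "nan" if np.isnan(mean) else f"{mean:.6f}"
                    fh.write(f"{factor}\t{cls}\t{off}\t{val}\t{n}\n")
    if cluster_labels is not None:
        with open(os.path.join(out, "clusters.tsv"), "w") as fh:
            fh.write("chromosome\tstart\tcluster\n")
            for h, lab in zip(bound_motifs, cluster_labels):
                fh.write(f"{h.chromosome}\t{h.start}\t{lab}\n")
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
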