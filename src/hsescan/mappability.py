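"""k-mer mappability tracks and the definition of the factor-free motif set.

A position is *unique* when the k-mer starting there (default k=40, the tag
length) occurs exactly once in the genome, counting forward and
reverse-complement occurrences jointly — a sequenced tag can originate from
either strand.  Free motifs are strong motif matches in fully mappable
flanking sequence (every 40-mer in the 400-base window on the motif unique)
that overlap no knockdown-validated peak: sites the assay *could* have
detected but did not.

Counting is exact hash-based k-mer counting (internal plumbing in place of a
suffix-index tool; production genomes may substitute an external mappability
track through the same interface).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from hsescan.motif import MotifHit, revcomp

logger = logging.getLogger(__name__)


@dataclass
class MappabilityTrack:
    """Per-position uniqueness flags for k-mers; ``unique[chrom][i]`` covers
    the k-mer starting at i (defined for 0 <= i <= L - k)."""

    k: int
    unique: dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        return len(self.unique[chrom]) + self.k - 1


def kmer_uniqueness(genome: Mapping[str, str] | str, k: int = 40) -> MappabilityTrack:
    """Exact strand-joint k-mer uniqueness for every start position.

    A start is unique iff its k-mer's canonical form (lexicographic min of the
    k-mer and its reverse complement) occurs exactly once among all start
    positions genome-wide.  k-mers containing N are never unique.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    counts: Counter[str] = Counter()
    per_chrom: dict[str, list[str]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        if k > len(seq):
            raise ValueError(f"k={k} exceeds length of {chrom} ({len(seq)})")
        kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        canon = [min(s, revcomp(s)) for s in kmers]
        per_chrom[chrom] = canon
        counts.update(canon)
    unique = {}
    for chrom, canon in per_chrom.items():
        flags = np.array([counts[c] == 1 and "N" not in c for c in canon], dtype=bool)
        unique[chrom] = flags
    return MappabilityTrack(k, unique)


def window_fully_mappable(
    track: MappabilityTrack, chromosome: str, motif_center: int, window: int = 400
) -> bool:
    """True iff every k-mer lying fully inside the window on the motif is unique.

    Windows clipped at a chromosome edge are conservatively non-mappable.
    """
    if window < track.k:
        raise ValueError("window must be >= k")
    flags = track.unique[chromosome]
    L = track.chrom_length(chromosome)
    ws = motif_center - window // 2
    we = ws + window
    if ws < 0 or we > L:
        logger.debug("mappability window at %s:%d clipped; treated as non-mappable",
                     chromosome, motif_center)
        return False
    return bool(flags[ws : we - track.k + 1].all())


def find_free_motifs(
    hits: Sequence[MotifHit],
    bound_assignments: Mapping,
    track: MappabilityTrack,
    p_threshold: float = 5e-6,
    window: int = 400,
) -> list[MotifHit]:
    """Select the factor-free motif set.

    Free motifs are hits with p-value <= ``p_threshold`` whose 400-base
    flanking window is fully mappable and which neither are assigned to nor
    overlap any knockdown-sensitive peak in ``bound_assignments`` (a map
    peak -> assigned hit or None).  The bound and free sets never intersect.
    """
    sensitive_peaks = [p for p in bound_assignments if p.is_sensitive]
    bound_hits = {
        id(h) for h in bound_assignments.values() if h is not None
    }
    free: list[MotifHit] = []
    for h in hits:
        if h.p_value > p_threshold:
            continue
        if id(h) in bound_hits:
            continue
        if any(
            p.chromosome == h.chromosome and h.start < p.end and p.start < h.end
            for p in sensitive_peaks
        ):
            continue
        if not window_fully_mappable(track, h.chromosome, h.center, window):
            continue
        free.append(h)
    return free


def write_nonunique_bed(track: MappabilityTrack, path) -> None:
    """Write non-unique start positions as merged BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(track.unique):
            flags = track.unique[chrom]
            bad = np.nonzero(~flags)[0]
            if len(bad) == 0:
                continue
            start = prev = int(bad[0])
            for i in bad[1:]:
                if i == prev + 1:
                    prev = int(i)
                    continue
                fh.write(f"{chrom}\t{start}\t{prev + 1}\tnonunique\n")
                start = prev = int(i)
            fh.write(f"{chrom}\t{start}\t{prev + 1}\tnonunique\n")
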