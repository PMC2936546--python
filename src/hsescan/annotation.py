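"""Annotation of motifs against gene models: promoter / genic / intergenic.

Promoters are the ``promoter_size`` bases (default 500) immediately upstream
of a TSS, strand-aware and not clipped by neighbouring gene bodies, so one
coordinate can be both inside a gene and in the promoter of a downstream
gene's TSS — the two classes overlap by design and class fractions may sum to
more than 1.  Intergenic means neither.  Coordinates 0-based half-open;
motifs are classified by their center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hsescan.motif import MotifHit


@dataclass(frozen=True)
class GeneModel:
    chromosome: str
    start: int
    end: int
    strand: str
    name: str = "gene"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.name}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter_interval(self, promoter_size: int = 500) -> tuple[int, int]:
        """Half-open upstream window of the TSS on the gene's strand."""
        if self.strand == "+":
            return (self.tss - promoter_size, self.tss)
        return (self.tss + 1, self.tss + 1 + promoter_size)


def classify_motif(
    motif: MotifHit | int,
    genes: Sequence[GeneModel],
    promoter_size: int = 500,
    chromosome: str | None = None,
) -> dict[str, bool]:
    """Flags {promoter, genic, intergenic} for a motif center.

    promoter and genic may both be true; intergenic excludes both.
    """
    if isinstance(motif, MotifHit):
        center, chrom = motif.center, motif.chromosome
    else:
        center, chrom = int(motif), chromosome
    promoter = False
    genic = False
    for g in genes:
        if chrom is not None and g.chromosome != chrom:
            continue
        if g.start <= center < g.end:
            genic = True
        ps, pe = g.promoter_interval(promoter_size)
        if ps <= center < pe:
            promoter = True
    return {"promoter": promoter, "genic": genic, "intergenic": not (promoter or genic)}


def class_composition(
    motifs: Sequence[MotifHit],
    genes: Sequence[GeneModel],
    promoter_size: int = 500,
) -> dict[str, dict[str, float]]:
    """Per-class counts and fractions over a motif set (classes overlap, so
    fractions may sum to more than 1)."""
    if len(motifs) == 0:
        raise ValueError("at least one motif is required")
    counts = {"promoter": 0, "genic": 0, "intergenic": 0, "promoter_and_genic": 0}
    for m in motifs:
        flags = classify_motif(m, genes, promoter_size)
        for cls in ("promoter", "genic", "intergenic"):
            counts[cls] += flags[cls]
        counts["promoter_and_genic"] += flags["promoter"] and flags["genic"]
    n = len(motifs)
    return {cls: {"count": c, "fraction": c / n} for cls, c in counts.items()}


def _union_length(intervals: list[tuple[int, int]], genome_length: int) -> int:
    clipped = [
        (max(0, s), min(genome_length, e)) for s, e in intervals if e > 0 and s < genome_length
    ]
    if not clipped:
        return 0
    clipped.sort()
    total = 0
    cs, ce = clipped[0]
    for s, e in clipped[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            total += ce - cs
            cs, ce = s, e
    return total + (ce - cs)


def genome_composition(
    genes: Sequence[GeneModel],
    genome_length: int,
    promoter_size: int = 500,
) -> dict[str, float]:
    """Fractions of the genome covered by gene bodies and by promoter windows.

    Base-pair union coverage per chromosome; promoter bases inside gene bodies
    still count toward the promoter fraction (overlapping-class accounting).
    For a multi-chromosome annotation pass the summed length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_chrom_genes: dict[str, list[tuple[int, int]]] = {}
    by_chrom_prom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chromosome, []).append((g.start, g.end))
        by_chrom_prom.setdefault(g.chromosome, []).append(g.promoter_interval(promoter_size))
    genic = sum(_union_length(v, genome_length) for v in by_chrom_genes.values())
    promoter = sum(_union_length(v, genome_length) for v in by_chrom_prom.values())
    return {
        "genic_fraction": genic / genome_length,
        "promoter_fraction": promoter / genome_length,
    }


# ----------------------------------------------------------------------
def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            size = g.end - g.start
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{size},\t0,\n"
            )


def read_genes_bed(path) -> list[GeneModel]:
    """Read gene models from BED6/BED12 (first six columns used)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else "gene"
            strand = f[5] if len(f) > 5 else "+"
            genes.append(GeneModel(f[0], int(f[1]), int(f[2]), strand, name))
    return genes
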