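"""Tag libraries: aligned 5'-end coordinates, normalized window counts, density tracks.

A *tag* is the uniquely aligned 5' end of one sequenced ChIP fragment:
(chromosome, position, strand).  All counts are normalized per 10 million
aligned tags in the library ("tags / 10 bp / 10 million sequences" for the
density tracks), so libraries of different depth are directly comparable.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

NORM = 1e7  # densities and window counts are per 10 million library tags


@dataclass
class TagLibrary:
    """Aligned tag 5'-end coordinates with strand, per chromosome.

    ``positions[chrom]`` is sorted; ``strands[chrom]`` is the parallel array
    of ``+``/``-`` labels.  ``library_total`` is the aligned-tag count used as
    the normalization denominator (defaults to the number of tags held).
    """

    library_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)
    library_total: int = 0

    @classmethod
    def from_tags(
        cls,
        library_id: str,
        tags: Iterable[tuple[str, int, str]],
        library_total: int | None = None,
    ) -> "TagLibrary":
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for chrom, pos, strand in tags:
            by_chrom.setdefault(chrom, []).append((int(pos), strand))
        positions, strands = {}, {}
        n = 0
        for chrom, recs in by_chrom.items():
            recs.sort()
            positions[chrom] = np.array([p for p, _ in recs], dtype=np.int64)
            strands[chrom] = np.array([s for _, s in recs])
            n += len(recs)
        total = n if library_total is None else int(library_total)
        if total < n:
            raise ValueError("library_total must be >= number of tags")
        lib = cls(library_id, positions, strands, total)
        if n == 0:
            logger.warning("library %s is empty", library_id)
        return lib

    @property
    def n_tags(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def chrom_span(self, chrom: str) -> int:
        """Largest tag coordinate + 1 (a lower bound on chromosome length)."""
        p = self.positions.get(chrom)
        return 0 if p is None or len(p) == 0 else int(p[-1]) + 1

    def raw_window_count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self.positions:
            raise KeyError(f"unknown chromosome {chrom!r} in library {self.library_id}")
        p = self.positions[chrom]
        return int(np.searchsorted(p, end, side="left") - np.searchsorted(p, start, side="left"))


@dataclass
class DensityTrack:
    """Binned, shifted, depth-normalized tag density (per 10 bp per 10M tags)."""

    library_id: str
    bin_width: int
    shift: int
    values: dict[str, np.ndarray]  # chrom -> densities, bin b covers [b*w, (b+1)*w)

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def window_count(lib: TagLibrary, chromosome: str, center: int, width: int) -> float:
    """Normalized count of tag 5' ends in the ``width``-base window on ``center``.

    The window is ``[center - width//2, center + width//2)`` (even widths put
    the center at the left of the middle pair); counts scale by
    ``1e7 / library_total``.  Windows running past the chromosome start are
    clipped (and logged).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    start = center - width // 2
    end = start + width
    if start < 0:
        logger.debug("window at %s:%d clipped at chromosome start", chromosome, center)
        start = 0
    n = lib.raw_window_count(chromosome, start, end)
    return n * NORM / lib.library_total


def density_track(lib: TagLibrary, shift: int, bin_width: int = 10) -> DensityTrack:
    """Shift tags toward the fragment center and bin the normalized density.

    Plus-strand tags move ``+shift``, minus-strand tags ``-shift`` (clipped at
    zero); each tag contributes ``1e7 / library_total`` to its bin.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    per_tag = NORM / lib.library_total
    values: dict[str, np.ndarray] = {}
    for chrom, pos in lib.positions.items():
        if len(pos) == 0:
            values[chrom] = np.zeros(0)
            continue
        sgn = np.where(lib.strands[chrom] == "+", 1, -1)
        shifted = np.maximum(pos + sgn * shift, 0)
        bins = shifted // bin_width
        values[chrom] = np.bincount(bins) * per_tag
    return DensityTrack(lib.library_id, bin_width, shift, values)


def replicate_correlation(
    peaks: Sequence,
    lib_a: TagLibrary,
    lib_b: TagLibrary,
    width: int = 300,
) -> float:
    """Pearson correlation of per-peak tag densities between two libraries.

    Each peak's density is its window count divided by the sum of the counts
    over all peak windows in that library (densities per library sum to 1).
    """
    if len(peaks) < 3:
        raise ValueError("at least 3 peaks are required")
    dens = []
    for lib in (lib_a, lib_b):
        counts = np.array(
            [window_count(lib, p.chromosome, p.center, width) for p in peaks]
        )
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"library {lib.library_id} has no tags in any peak window; "
                "correlation undefined"
            )
        dens.append(counts / total)
    r, _ = stats.pearsonr(dens[0], dens[1])
    return float(r)


# ----------------------------------------------------------------------
# BED I/O.  A tag is written as a 1-base interval, so the 5' end is `start`
# on the plus strand and `end - 1` on the minus strand.

def write_tags_bed(lib: TagLibrary, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lib.positions):
            for pos, strand in zip(lib.positions[chrom], lib.strands[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{lib.library_id}\t0\t{strand}\n")


def read_tags_bed(path, library_id: str | None = None, library_total: int | None = None) -> TagLibrary:
    tags = []
    name = library_id
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            if name is None and len(f) > 3:
                name = f[3]
            pos = start if strand == "+" else end - 1
            tags.append((chrom, pos, strand))
    return TagLibrary.from_tags(name or "library", tags, library_total=library_total)


def write_bedgraph(track: DensityTrack, path, chrom_order: Sequence[str] | None = None) -> None:
    chroms = chrom_order if chrom_order is not None else sorted(track.values)
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in chroms:
            vals = track.values[chrom]
            for b in np.nonzero(vals)[0]:
                fh.write(f"{chrom}\t{b * w}\t{(b + 1) * w}\t{vals[b]:.6f}\n")
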