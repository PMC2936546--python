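"""Peak reconciliation and RNAi-sensitivity filtering.

The specificity filter at the heart of the pipeline: every candidate peak is
re-measured in a factor-depleted (RNAi knockdown) ChIP-seq library, and only
peaks whose signal collapses under depletion are kept.  Two criteria mirror
the published procedure:

1. the peak is also called in the knockdown data and its experimental/knockdown
   intensity ratio exceeds the depletion observed at a high-affinity reference
   locus (the Hsp83 promoter in the study; its signal fell below 70% of
   control, so the default reference ratio is 1/0.7);
2. the peak is absent from the knockdown calls and the corresponding region is
   depleted at least ``min_fold`` (default 3).

Intensity is the normalized count of tag 5' ends in a 240-base window on the
experimental peak center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hsescan.tag_io import TagLibrary, window_count

logger = logging.getLogger(__name__)

SENSITIVE_1 = "sensitive_criterion1"
SENSITIVE_2 = "sensitive_criterion2"
RESISTANT = "resistant"
UNCLASSIFIED = "unclassified"

DEFAULT_REFERENCE_DEPLETION = 1.0 / 0.7  # reference-locus signal fell below 70%


@dataclass(frozen=True)
class Peak:
    """A candidate binding event: summit, boundaries, provenance, classification."""

    chromosome: str
    center: int
    start: int
    end: int
    caller: str = "caller_A"
    fdr: float = 0.0
    intensity_exp: float | None = None
    intensity_kd: float | None = None
    classification: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if not (self.start <= self.center < self.end):
            raise ValueError(
                f"summit {self.center} outside boundary [{self.start},{self.end})"
            )
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0,1], got {self.fdr}")

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def is_sensitive(self) -> bool:
        return self.classification in (SENSITIVE_1, SENSITIVE_2)


# ----------------------------------------------------------------------
def call_windows_poisson(
    lib: TagLibrary,
    background: TagLibrary,
    window: int = 200,
    fdr_cutoff: float = 0.05,
    step: int | None = None,
    genome_length: int | None = None,
    summit_bin: int = 10,
    caller: str = "caller_A",
    shift: int = 0,
) -> list[Peak]:
    """Sliding-window Poisson peak caller (plumbing for synthetic runs).

    Production inputs are peak calls from external callers; this internal
    substitute lets synthetic pipelines run end to end.  Each window's tag
    count is tested against a Poisson expectation scaled from the background
    library (floored at the background's genome-wide rate), p-values are
    Benjamini-Hochberg adjusted, significant windows are merged, and each
    merged region's summit is its maximum-count ``summit_bin`` bin.  ``shift``
    moves 5' ends toward the fragment center (strand-aware) before counting,
    so summits land on the binding site rather than on the two 5'-end modes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = step or max(1, window // 2)
    peaks: list[Peak] = []
    for chrom in sorted(lib.positions):
        L = genome_length or max(lib.chrom_span(chrom), background.chrom_span(chrom))
        if L < window:
            continue
        starts = np.arange(0, L - window + 1, step)
        p = lib.positions[chrom]
        if shift:
            sgn = np.where(lib.strands[chrom] == "+", 1, -1)
            p = np.sort(np.clip(p + sgn * shift, 0, L - 1))
        counts = np.searchsorted(p, starts + window) - np.searchsorted(p, starts)
        if background.n_tags == 0:
            logger.warning("empty background library; using uniform expectation")
            mu = np.full(len(starts), lib.n_tags * window / L)
        else:
            bp = background.positions.get(chrom, np.zeros(0, dtype=np.int64))
            bcounts = np.searchsorted(bp, starts + window) - np.searchsorted(bp, starts)
            floor = background.n_tags * window / L
            mu = np.maximum(bcounts, floor) * (lib.n_tags / background.n_tags)
        pvals = stats.poisson.sf(counts - 1, mu)
        if fdr_cutoff <= 0:
            continue
        reject, padj, _, _ = multipletests(pvals, alpha=fdr_cutoff, method="fdr_bh")
        sig = np.nonzero(reject)[0]
        if len(sig) == 0:
            continue
        # merge overlapping/adjacent significant windows
        regions: list[list] = []
        for i in sig:
            s, e, q = int(starts[i]), int(starts[i] + window), float(padj[i])
            if regions and s <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], e)
                regions[-1][2] = min(regions[-1][2], q)
            else:
                regions.append([s, e, q])
        for s, e, q in regions:
            edges = np.arange(s, e + summit_bin, summit_bin)
            hist, _ = np.histogram(p[(p >= s) & (p < e)], bins=edges)
            summit = int(edges[int(np.argmax(hist))] + summit_bin // 2)
            summit = min(max(summit, s), e - 1)
            peaks.append(
                Peak(chromosome=chrom, center=summit, start=s, end=e, caller=caller, fdr=q)
            )
    return peaks


def reconcile_callers(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> list[Peak]:
    """Merge a region caller's peaks (A, boundaries) with a point caller's (B, centers).

    A and B called the same peak when B's center falls inside A's boundary;
    the merged peak takes its center from B and boundary from A.  A center
    inside two boundaries goes to the boundary whose own center is nearest.
    Unmatched peaks from either caller are retained as candidates.
    """
    merged: list[Peak] = []
    matched_a: set[int] = set()
    for b in peaks_b:
        best_i = None
        best_d = None
        for i, a in enumerate(peaks_a):
            if a.chromosome == b.chromosome and a.start <= b.center < a.end:
                d = abs(b.center - a.center)
                if best_i is None or d < best_d:
                    best_i, best_d = i, d
        if best_i is None:
            merged.append(replace(b, caller="caller_B"))
        else:
            if best_i in matched_a:
                logger.debug("region peak %d matched by multiple point peaks", best_i)
            matched_a.add(best_i)
            a = peaks_a[best_i]
            merged.append(
                Peak(
                    chromosome=b.chromosome,
                    center=b.center,
                    start=a.start,
                    end=a.end,
                    caller="both",
                    fdr=min(a.fdr, b.fdr),
                )
            )
    for i, a in enumerate(peaks_a):
        if i not in matched_a:
            merged.append(replace(a, caller="caller_A"))
    merged.sort(key=lambda p: (p.chromosome, p.start, p.center))
    return merged


def classify_rnai_sensitivity(
    candidates: Sequence[Peak],
    kd_peaks: Sequence[Peak],
    lib_exp: TagLibrary,
    lib_kd: TagLibrary,
    reference_depletion: float | None = DEFAULT_REFERENCE_DEPLETION,
    window: int = 240,
    min_fold: float = 3.0,
    pseudocount: float = 1.0,
) -> list[Peak]:
    """Classify each candidate as knockdown-sensitive (genuine) or resistant.

    Depletion is ``intensity_exp / intensity_kd`` over the ``window``-base
    window on the experimental center; a zero knockdown count adds
    ``pseudocount`` normalized units to both numerator and denominator.  When
    ``reference_depletion`` is None it is computed from the strongest
    candidate (highest experimental intensity), mirroring the use of the
    highest-affinity locus as the depletion anchor.
    """
    if reference_depletion is not None and reference_depletion < 1:
        raise ValueError("reference_depletion must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")

    exp_i = np.array(
        [window_count(lib_exp, p.chromosome, p.center, window) for p in candidates]
    )
    kd_i = np.array(
        [window_count(lib_kd, p.chromosome, p.center, window) for p in candidates]
    )
    depletion = np.where(
        kd_i > 0, exp_i / np.where(kd_i > 0, kd_i, 1.0), (exp_i + pseudocount) / pseudocount
    )
    if np.any(kd_i == 0):
        logger.debug("%d peaks had zero knockdown counts; pseudocount applied", int((kd_i == 0).sum()))

    if reference_depletion is None:
        if len(candidates) == 0:
            raise ValueError("cannot infer reference depletion from an empty candidate list")
        ref_idx = int(np.argmax(exp_i))
        reference_depletion = float(depletion[ref_idx])
        logger.info(
            "reference depletion %.3f taken from strongest candidate at %s:%d",
            reference_depletion,
            candidates[ref_idx].chromosome,
            candidates[ref_idx].center,
        )

    out: list[Peak] = []
    for peak, ie, ik, dep in zip(candidates, exp_i, kd_i, depletion):
        called_in_kd = any(peak.overlaps(k) for k in kd_peaks)
        if called_in_kd and dep > reference_depletion:
            cls = SENSITIVE_1
        elif not called_in_kd and dep >= min_fold:
            cls = SENSITIVE_2
        else:
            cls = RESISTANT
        out.append(
            replace(
                peak,
                intensity_exp=float(ie),
                intensity_kd=float(ik),
                classification=cls,
            )
        )
    return out


def ex_kd_ratio_distribution(
    regions: Sequence[tuple[str, int]],
    lib_exp: TagLibrary,
    lib_kd: TagLibrary,
    window: int = 240,
    n_random: int = 1000,
    seed: int = 0,
    genome_length: int | None = None,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Experimental/knockdown signal ratios versus a matched random null.

    Returns per-region Ex/KD ratios, ratios at ``n_random`` uniformly drawn
    coordinates, and the fraction of region ratios lying below the null's
    95th percentile (regions drawn from the null itself give ~0.95; strongly
    depleted regions give ~0).
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)

    def ratio(chrom: str, center: int) -> float:
        e = window_count(lib_exp, chrom, center, window)
        k = window_count(lib_kd, chrom, center, window)
        if k == 0:
            return (e + pseudocount) / pseudocount
        return e / k

    ratios = np.array([ratio(c, pos) for c, pos in regions])
    chroms = sorted(lib_exp.positions)
    spans = {c: genome_length or lib_exp.chrom_span(c) for c in chroms}
    rand = []
    for _ in range(n_random):
        c = chroms[int(rng.integers(len(chroms)))]
        rand.append(ratio(c, int(rng.integers(spans[c]))))
    random_ratios = np.array(rand)
    upper = np.quantile(random_ratios, 0.95)
    fraction_below = float(np.mean(ratios < upper)) if len(ratios) else float("nan")
    return ratios, random_ratios, fraction_below


# ----------------------------------------------------------------------
# BED6+ I/O: chrom, start, end, name, -log10 FDR (capped), ".", center,
# caller, classification, intensity_exp, intensity_kd

def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = min(-np.log10(p.fdr) if p.fdr > 0 else 999.0, 999.0)
            ie = "." if p.intensity_exp is None else f"{p.intensity_exp:.4f}"
            ik = "." if p.intensity_kd is None else f"{p.intensity_kd:.4f}"
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\tpeak_{i}\t{score:.3f}\t.\t"
                f"{p.center}\t{p.caller}\t{p.classification}\t{ie}\t{ik}\n"
            )


def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            fdr = 10 ** (-float(f[4])) if len(f) > 4 else 0.0
            center = int(f[6]) if len(f) > 6 else (start + end) // 2
            caller = f[7] if len(f) > 7 else "caller_A"
            cls = f[8] if len(f) > 8 else UNCLASSIFIED
            ie = None if len(f) <= 9 or f[9] == "." else float(f[9])
            ik = None if len(f) <= 10 or f[10] == "." else float(f[10])
            peaks.append(
                Peak(chrom, center, start, end, caller, min(fdr, 1.0), ie, ik, cls)
            )
    return peaks
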