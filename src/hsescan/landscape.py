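"""Chromatin-landscape profiling and association around motifs.

Probe-level tracks (tiling-array style: position + intensity, plus intervals
called as regions of significant enrichment) are profiled around bound versus
free motifs in 100-base windows stepped by 50, tested for association by
Fisher's exact test on the 2x2 bound/free x enriched/unenriched table, and
summarized per motif as the mean probe intensity in a 400-base window for
k-means clustering (five clusters by default) and correlation against factor
binding intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from hsescan.motif import MotifHit
from hsescan.tag_io import TagLibrary, window_count

logger = logging.getLogger(__name__)


@dataclass
class ChromatinTrack:
    """One factor/modification: sorted probe intensities + enriched intervals."""

    factor: str
    positions: dict[str, np.ndarray]
    intensities: dict[str, np.ndarray]
    enriched_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if np.any(np.diff(pos) < 0):
                order = np.argsort(pos, kind="stable")
                self.positions[chrom] = pos[order]
                self.intensities[chrom] = self.intensities[chrom][order]
        self.enriched_regions = _normalize_regions(self.enriched_regions)

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions.get(chrom)
        if pos is None:
            return np.zeros(0)
        i, j = np.searchsorted(pos, (start, end))
        return self.intensities[chrom][i:j]


def _normalize_regions(regions: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping intervals per chromosome."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return out


@dataclass
class CompositeProfile:
    """Motif-centered average track intensity at fixed offsets."""

    factor: str
    offsets: np.ndarray
    mean_intensity: np.ndarray
    n_motifs: np.ndarray  # motifs contributing at each offset
    window: int
    step: int


@dataclass
class AssociationResult:
    """Fisher exact association of enrichment with bound vs free class."""

    factor: str
    table: np.ndarray  # [[bound_enr, bound_not], [free_enr, free_not]]
    odds_ratio: float
    p_value: float


# ----------------------------------------------------------------------
def composite_profile(
    track: ChromatinTrack,
    motifs: Sequence[MotifHit],
    span: int = 2000,
    window: int = 100,
    step: int = 50,
) -> CompositeProfile:
    """Mean track intensity in ``window``-base windows stepped by ``step``
    across +/- ``span`` around the motifs.

    Each motif contributes its window's mean probe intensity with equal
    weight regardless of probe count; offsets are strand-flipped so profiles
    are motif-oriented.  Motifs with no probe in a window are omitted from
    that offset's mean (their count is reported).
    """
    if window < step:
        raise ValueError("window must be >= step")
    offsets = np.arange(-span, span + 1, step)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=int)
    for m in motifs:
        sign = -1 if m.strand == "-" else 1
        for i, off in enumerate(offsets):
            c = m.center + sign * int(off)
            vals = track.probes_in(m.chromosome, c - window // 2, c - window // 2 + window)
            if len(vals):
                sums[i] += vals.mean()
                counts[i] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CompositeProfile(track.factor, offsets, means, counts, window, step)


def window_mean_intensity(
    track: ChromatinTrack, motif: MotifHit, window: int = 400
) -> float:
    """Mean probe intensity in the window on the motif; NaN when probe-free."""
    if window <= 0:
        raise ValueError("window must be positive")
    s = motif.center - window // 2
    vals = track.probes_in(motif.chromosome, s, s + window)
    return float(vals.mean()) if len(vals) else float("nan")


def enrichment_membership(motif: MotifHit, regions: Sequence[tuple[str, int, int]]) -> bool:
    """True iff the motif center lies inside any (half-open) enriched region."""
    return any(
        chrom == motif.chromosome and s <= motif.center < e for chrom, s, e in regions
    )


def fisher_test_table(table: np.ndarray, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table; returns (odds_ratio, p).

    The odds ratio uses the Haldane-Anscombe +0.5 correction when any cell is
    zero; the p-value is the exact conditional (hypergeometric) tail sum.
    """
    table = np.asarray(table, dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative=alternative)
    if np.any(table == 0):
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return odds, float(p)


def fisher_association(
    bound_flags: Sequence[bool],
    free_flags: Sequence[bool],
    factor: str = "factor",
    alternative: str = "two-sided",
) -> AssociationResult:
    """Fisher's exact test of enrichment membership, bound versus free motifs."""
    if len(bound_flags) == 0 or len(free_flags) == 0:
        raise ValueError("both motif classes must be non-empty")
    b = np.asarray(bound_flags, dtype=bool)
    f = np.asarray(free_flags, dtype=bool)
    table = np.array(
        [[int(b.sum()), int((~b).sum())], [int(f.sum()), int((~f).sum())]], dtype=np.int64
    )
    odds, p = fisher_test_table(table, alternative)
    return AssociationResult(factor, table, odds, p)


def associate_factors(
    tracks: Mapping[str, ChromatinTrack],
    bound: Sequence[MotifHit],
    free: Sequence[MotifHit],
    alternative: str = "two-sided",
) -> list[dict]:
    """Per-factor association table (counts, odds ratio, p, BH-adjusted p)."""
    results = []
    for factor in sorted(tracks):
        track = tracks[factor]
        bflags = [enrichment_membership(m, track.enriched_regions) for m in bound]
        fflags = [enrichment_membership(m, track.enriched_regions) for m in free]
        res = fisher_association(bflags, fflags, factor=factor, alternative=alternative)
        results.append(
            {
                "factor": factor,
                "bound_enriched": int(res.table[0, 0]),
                "bound_total": len(bound),
                "free_enriched": int(res.table[1, 0]),
                "free_total": len(free),
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    if results:
        padj = multipletests([r["p_value"] for r in results], method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r["p_adjusted_bh"] = float(q)
    return results


# ----------------------------------------------------------------------
def intensity_matrix(
    tracks: Mapping[str, ChromatinTrack],
    motifs: Sequence[MotifHit],
    window: int = 400,
) -> tuple[np.ndarray, list[str]]:
    """Motifs x factors matrix of 400-base mean probe intensities (NaN = no probe)."""
    factors = sorted(tracks)
    mat = np.full((len(motifs), len(factors)), np.nan)
    for j, factor in enumerate(factors):
        for i, m in enumerate(motifs):
            mat[i, j] = window_mean_intensity(tracks[factor], m, window)
    return mat, factors


def cluster_motifs(
    matrix: np.ndarray,
    k: int = 5,
    restarts: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on the motif x factor intensity matrix.

    Missing values are imputed with the column mean, columns are z-scored by
    default, and the best of ``restarts`` seeded initializations by
    within-cluster sum of squares is kept.  Rows are presented to the solver
    in a canonical (lexicographic) order and clusters are relabelled by
    centroid norm, so the result is invariant to motif input order under a
    fixed seed.  Returns (labels, centroids) with centroids on the
    standardized scale.
    """
    X = np.array(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (motifs x factors)")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of motifs ({n})")
    col_mean = np.nanmean(X, axis=0)
    missing = np.isnan(X)
    if missing.any():
        logger.info("imputing %d missing intensities with column means", int(missing.sum()))
        X[missing] = np.take(col_mean, np.nonzero(missing)[1])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    order = np.lexsort(X.T[::-1])  # canonical row order: sort by first column, then next
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels_sorted = km.fit_predict(X[order])
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    # relabel clusters deterministically by centroid (norm, then coords)
    cents = km.cluster_centers_
    rank = sorted(range(k), key=lambda c: (float(np.linalg.norm(cents[c])), tuple(cents[c])))
    remap = {old: new for new, old in enumerate(rank)}
    labels = np.array([remap[l] for l in labels])
    centroids = cents[rank]
    return labels, centroids


def intensity_binding_correlation(
    track: ChromatinTrack,
    motifs_enriched_only: Sequence[MotifHit],
    hsf_lib: TagLibrary,
    hsf_window: int = 240,
    intensity_window: int = 400,
) -> tuple[float, float]:
    """Pearson r between track intensity and factor binding intensity at motifs.

    Track intensity is the 400-base mean probe intensity; binding intensity is
    the normalized tag count in the 240-base window on the motif.  Computed
    only over motifs enriched for the factor (caller pre-filters).
    """
    x, y = [], []
    for m in motifs_enriched_only:
        xi = window_mean_intensity(track, m, intensity_window)
        if np.isnan(xi):
            continue
        x.append(xi)
        y.append(window_count(hsf_lib, m.chromosome, m.center, hsf_window))
    if len(x) < 3:
        raise ValueError("at least 3 motifs with probe coverage are required")
    x = np.array(x)
    y = np.array(y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quartile_intensity(
    motifs: Sequence[MotifHit],
    hsf_lib: TagLibrary,
    window: int = 240,
) -> dict[str, np.ndarray]:
    """Binding-intensity distributions for motif p-value quartiles.

    Motifs are split into quartiles of their match p-value (most significant
    first); each motif's normalized window count is divided by the number of
    listed motifs whose centers fall in its window (multi-motif windows share
    their tags).  Degenerate case: all p-values equal returns a single group.
    """
    if len(motifs) < 4:
        raise ValueError("at least 4 motifs are required")
    pvals = np.array([m.p_value for m in motifs])
    centers_by_chrom: dict[str, np.ndarray] = {}
    for m in motifs:
        centers_by_chrom.setdefault(m.chromosome, [])
    for chrom in centers_by_chrom:
        centers_by_chrom[chrom] = np.sort(
            np.array([m.center for m in motifs if m.chromosome == chrom])
        )

    def norm_count(m: MotifHit) -> float:
        c = window_count(hsf_lib, m.chromosome, m.center, window)
        cs = centers_by_chrom[m.chromosome]
        s = m.center - window // 2
        n_in = int(np.searchsorted(cs, s + window) - np.searchsorted(cs, s))
        return c / max(n_in, 1)

    counts = np.array([norm_count(m) for m in motifs])
    if np.unique(pvals).size == 1:
        return {"all": counts}
    order = np.argsort(pvals, kind="stable")
    groups = np.array_split(order, 4)
    names = ["q1_most_significant", "q2", "q3", "q4_least_significant"]
    return {name: counts[idx] for name, idx in zip(names, groups)}


# ----------------------------------------------------------------------
def read_track_bedgraph(path, factor: str, regions_path=None) -> ChromatinTrack:
    """Read probe intensities from bedGraph (probe position = interval start)
    and optional enriched regions from BED."""
    pos: dict[str, list[int]] = {}
    inten: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            pos.setdefault(f[0], []).append(int(f[1]))
            inten.setdefault(f[0], []).append(float(f[3]))
    regions: list[tuple[str, int, int]] = []
    if regions_path is not None:
        with open(regions_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                regions.append((f[0], int(f[1]), int(f[2])))
    return ChromatinTrack(
        factor,
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=float) for c, v in inten.items()},
        regions,
    )


def write_track_bedgraph(track: ChromatinTrack, path, regions_path=None) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for p, v in zip(track.positions[chrom], track.intensities[chrom]):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6f}\n")
    if regions_path is not None:
        with open(regions_path, "w") as fh:
            for chrom, s, e in track.enriched_regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{track.factor}_enriched\n")
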