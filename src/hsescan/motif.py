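"""HSE position-specific weight matrices: construction, scoring, exact p-values, scanning.

The HSE (heat-shock element) is a tandem array of three inverted-repeat 5-bp
units of the AGAAN type; the matrices built here are generic, the HSE only
supplies the default seed used for discovery (:func:`hse_seed_pswm`).

Scores are log-odds in bits against a 0-order background model.  Log-odds are
quantized to ``score_granularity`` (default 1e-3 bits) when the matrix is
built, so the dynamic-programming p-value lattice and the scanner share one
score space and ``score_pvalue`` is exact for every score the scanner can
produce (up to float summation error), not an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer sentinel for -inf scores (N bases, zero-probability cells); large
# enough that one per window forces the window below any achievable score
_NEG = -(1 << 40)


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A genomic motif occurrence with its score and background p-value."""

    chromosome: str
    start: int
    strand: str
    sequence: str
    score: float
    p_value: float
    distance_to_peak_center: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0,1], got {self.p_value}")

    @property
    def width(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def center(self) -> int:
        return self.start + self.width // 2


class PSWM:
    """Position-specific weight matrix with background model and exact p-values.

    Parameters
    ----------
    probabilities:
        (width, 4) array of per-position base probabilities (A, C, G, T);
        each row must sum to 1 within 1e-9.
    background:
        length-4 background base distribution; uniform if omitted.
    pseudocount:
        total pseudocount mass recorded for provenance (the matrix is assumed
        already regularized by :func:`build_pswm`).
    score_granularity:
        lattice step, in bits, to which log-odds are rounded.
    """

    def __init__(
        self,
        probabilities: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.25,
        score_granularity: float = 1e-3,
        name: str = "motif",
    ) -> None:
        probs = np.asarray(probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probabilities must have shape (width, 4)")
        if probs.shape[0] < 1:
            raise ValueError("width must be >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(bg <= 0):
            raise ValueError("background probabilities must be positive")
        if score_granularity <= 0:
            raise ValueError("score_granularity must be positive")

        self.probabilities = probs
        self.background = bg
        self.pseudocount = float(pseudocount)
        self.score_granularity = float(score_granularity)
        self.name = name

        with np.errstate(divide="ignore"):
            raw = np.log2(probs / bg)
        # integer lattice scores; -inf cells get the sentinel
        iscores = np.full(probs.shape, _NEG, dtype=np.int64)
        finite = np.isfinite(raw)
        iscores[finite] = np.rint(raw[finite] / score_granularity).astype(np.int64)
        self._iscores = iscores
        self.logodds = np.where(finite, iscores * score_granularity, -np.inf)

        self._sf_cache: tuple[int, int, float, np.ndarray] | None = None

    # ------------------------------------------------------------------
    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def reverse_complement(self) -> "PSWM":
        """Matrix scoring the reverse-complement strand at the same footprint."""
        return PSWM(
            self.probabilities[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            score_granularity=self.score_granularity,
            name=self.name + "_rc",
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    # ------------------------------------------------------------------
    def score(self, window: str, strand: str = "+") -> float:
        """Log-odds score (bits) of one window; -inf if it contains N."""
        if len(window) != self.width:
            raise ValueError(
                f"window length {len(window)} does not match matrix width {self.width}"
            )
        if strand == "-":
            window = revcomp(window)
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        enc = encode(window)
        if np.any(enc == 4):
            return -np.inf
        total = int(self._iscores[np.arange(self.width), enc].sum())
        if total <= _NEG // 2:
            return -np.inf
        return total * self.score_granularity

    # ------------------------------------------------------------------
    def _survival(self) -> tuple[int, int, float, np.ndarray]:
        """Exact distribution of the lattice score of a random background window.

        Returns (lo, hi, p_dead, sf) where sf[k - lo] = P(score >= k*g) for
        integer lattice scores k in [lo, hi], and p_dead is the probability
        mass on -inf (zero-probability cells).
        """
        if self._sf_cache is not None:
            return self._sf_cache
        bg = self.background
        dist = np.array([1.0])
        lo = 0
        p_alive = 1.0
        for pos in range(self.width):
            row = self._iscores[pos]
            finite = row > _NEG // 2
            if not np.any(finite):
                # every base is a dead cell: all mass goes to -inf
                dist = np.array([0.0])
                p_alive = 0.0
                break
            vals = row[finite]
            ps = bg[finite]
            p_alive *= float(ps.sum())
            vmin, vmax = int(vals.min()), int(vals.max())
            new = np.zeros(len(dist) + (vmax - vmin), dtype=float)
            for v, p in zip(vals, ps):
                new[v - vmin : v - vmin + len(dist)] += p * dist
            dist = new
            lo += vmin
        hi = lo + len(dist) - 1
        sf = np.cumsum(dist[::-1])[::-1]
        p_dead = max(0.0, 1.0 - p_alive)
        self._sf_cache = (lo, hi, p_dead, sf)
        return self._sf_cache

    def pvalue(self, score: float) -> float:
        """P(random background window scores >= ``score``), exact on the lattice."""
        if score == -np.inf:
            return 1.0
        if score == np.inf:
            return 0.0
        lo, hi, p_dead, sf = self._survival()
        k = int(round(score / self.score_granularity))
        if k > hi:
            return 0.0
        if k <= lo:
            return float(sf[0]) if k == lo else 1.0 - p_dead
        return float(sf[k - lo])

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest lattice score whose p-value is <= ``p_threshold``.

        Returns +inf when no achievable score is that significant.
        """
        if not (0.0 < p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0,1)")
        lo, hi, _, sf = self._survival()
        idx = np.searchsorted(-sf, -p_threshold, side="left")
        if idx >= len(sf):
            return np.inf
        return (lo + int(idx)) * self.score_granularity


# ----------------------------------------------------------------------
def build_pswm(
    occurrences: Sequence[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 0.25,
    score_granularity: float = 1e-3,
    name: str = "motif",
) -> PSWM:
    """Build a PSWM from aligned equal-length occurrences.

    Probabilities are ``(counts + pseudocount * background) / (n + pseudocount)``
    per position, with N bases excluded from both counts and n.
    """
    if len(occurrences) == 0:
        raise ValueError("at least one occurrence is required")
    width = len(occurrences[0])
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4), dtype=float)
    n_eff = np.zeros(width, dtype=float)
    for seq in occurrences:
        if len(seq) != width:
            raise ValueError(f"occurrence {seq!r} has length {len(seq)}, expected {width}")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"occurrence {seq!r} contains non-ACGTN symbols {sorted(bad)}")
        enc = encode(seq)
        for pos, code in enumerate(enc):
            if code < 4:
                counts[pos, code] += 1.0
                n_eff[pos] += 1.0
    if np.any(n_eff + pseudocount == 0):
        raise ValueError("a position has no informative (non-N) bases and no pseudocount")
    probs = (counts + pseudocount * bg) / (n_eff + pseudocount)[:, None]
    return PSWM(probs, bg, pseudocount=pseudocount, score_granularity=score_granularity, name=name)


def score_sequence(pswm: PSWM, window: str, strand: str = "+") -> float:
    return pswm.score(window, strand)


def score_pvalue(pswm: PSWM, score: float) -> float:
    return pswm.pvalue(score)


# ----------------------------------------------------------------------
def _scan_one_strand(enc: np.ndarray, iscores: np.ndarray) -> np.ndarray:
    """Integer lattice scores of every window start on the encoded sequence."""
    width = iscores.shape[0]
    n_windows = len(enc) - width + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int64)
    # column 4 (N) is a dead cell on every row
    table = np.hstack([iscores, np.full((width, 1), _NEG, dtype=np.int64)])
    totals = np.zeros(n_windows, dtype=np.int64)
    for j in range(width):
        totals += table[j, enc[j : j + n_windows]]
    return totals


def scan_genome(
    genome: Mapping[str, str] | str,
    pswm: PSWM,
    p_threshold: float,
    collapse_overlap: float = 0.5,
) -> list[MotifHit]:
    """Report every window on either strand with p-value <= ``p_threshold``.

    Opposite-strand hits whose footprints overlap by at least
    ``collapse_overlap`` of the width are collapsed to the better-scoring
    strand (ties keep the plus strand).  Returned hits are sorted by
    (chromosome, start).
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0,1)")
    width = pswm.width
    g = pswm.score_granularity
    thr = pswm.score_threshold(p_threshold)
    if thr == np.inf:
        return []
    kthr = int(round(thr / g))
    rc = pswm.reverse_complement()

    hits: list[MotifHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        if len(seq) < width:
            continue
        enc = encode(seq)
        tot_f = _scan_one_strand(enc, pswm._iscores)
        tot_r = _scan_one_strand(enc, rc._iscores)
        cand: list[tuple[int, str, int]] = []  # (start, strand, lattice score)
        for i in np.nonzero(tot_f >= kthr)[0]:
            cand.append((int(i), "+", int(tot_f[i])))
        for i in np.nonzero(tot_r >= kthr)[0]:
            cand.append((int(i), "-", int(tot_r[i])))
        cand.sort(key=lambda c: (c[0], c[1]))
        def oriented(c: tuple[int, str, int]) -> str:
            s = seq[c[0] : c[0] + width]
            return s if c[1] == "+" else revcomp(s)

        def better(a: tuple[int, str, int], b: tuple[int, str, int]):
            if a[2] != b[2]:
                return a if a[2] > b[2] else b
            # score tie: lexicographically smaller oriented sequence, a
            # reverse-complement-invariant choice; '+' breaks exact palindromes
            sa, sb = oriented(a), oriented(b)
            if sa != sb:
                return a if sa < sb else b
            return a if a[1] == "+" else b

        # greedy collapse of opposite-strand near-duplicates
        kept: list[tuple[int, str, int]] = []
        for c in cand:
            if kept:
                last = kept[-1]
                if last[1] != c[1] and (width - (c[0] - last[0])) / width >= collapse_overlap:
                    kept[-1] = better(last, c)
                    continue
            kept.append(c)
        for start, strand, k in kept:
            score = k * g
            hits.append(
                MotifHit(
                    chromosome=chrom,
                    start=start,
                    strand=strand,
                    sequence=seq[start : start + width],
                    score=score,
                    p_value=pswm.pvalue(score),
                )
            )
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return hits


# ----------------------------------------------------------------------
def assign_peak_motifs(
    peaks: Sequence,
    hits: Sequence[MotifHit],
    p_threshold: float = 1e-3,
    search_halfwidth: int = 60,
    rng: np.random.Generator | None = None,
    genome_length: int | None = None,
):
    """Assign to each peak the qualifying motif hit nearest its center.

    Peaks with no qualifying hit within ``search_halfwidth`` bases are mapped
    to ``None`` (motif-free).  Ties are broken by higher score, then lower
    coordinate.  Returns ``(assignments, distances, random_distances)`` where
    distances are peak center minus motif center for assigned peaks, and
    random_distances is the matched random-coordinate null (nearest-hit
    distance from uniformly drawn centers; empty unless ``rng`` and
    ``genome_length`` are given).
    """
    qual = [h for h in hits if h.p_value <= p_threshold]
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in qual:
        by_chrom.setdefault(h.chromosome, []).append(h)
    centers = {c: np.array([h.center for h in hs]) for c, hs in by_chrom.items()}

    def nearest(chrom: str, pos: int) -> MotifHit | None:
        hs = by_chrom.get(chrom)
        if not hs:
            return None
        cs = centers[chrom]
        i = int(np.searchsorted(cs, pos))
        best: MotifHit | None = None
        best_key = None
        for j in range(max(0, i - 2), min(len(hs), i + 2)):
            h = hs[j]
            d = abs(pos - h.center)
            key = (d, -h.score, h.start)
            if best is None or key < best_key:
                best, best_key = h, key
        return best

    assignments: dict = {}
    distances: list[int] = []
    for peak in peaks:
        h = nearest(peak.chromosome, peak.center)
        if h is not None and abs(peak.center - h.center) <= search_halfwidth:
            assignments[peak] = h
            distances.append(peak.center - h.center)
        else:
            assignments[peak] = None

    random_distances: list[int] = []
    if rng is not None and genome_length is not None and by_chrom:
        chroms = sorted(by_chrom)
        for _ in range(max(len(peaks), 1)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(genome_length))
            h = nearest(chrom, pos)
            if h is not None:
                random_distances.append(pos - h.center)
    return assignments, np.array(distances), np.array(random_distances)


# ----------------------------------------------------------------------
# Seed-consensus discovery (internal plumbing standing in for de novo
# discovery with MEME, which production runs would use on the same windows).

HSE_SEED = "NTTCNNGAANNTTCN"


def consensus_pswm(
    consensus: str,
    match_prob: float = 0.94,
    background: Sequence[float] | None = None,
    score_granularity: float = 1e-3,
    name: str = "consensus",
) -> PSWM:
    """Sharp PSWM from an IUPAC-free consensus; N positions take the background."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    rows = []
    for ch in consensus.upper():
        if ch == "N":
            rows.append(bg.copy())
        elif ch in BASES:
            row = np.full(4, (1.0 - match_prob) / 3.0)
            row[BASES.index(ch)] = match_prob
            rows.append(row)
        else:
            raise ValueError(f"consensus may contain only ACGTN, got {ch!r}")
    return PSWM(np.array(rows), bg, pseudocount=0.0, score_granularity=score_granularity, name=name)


def hse_seed_pswm(background: Sequence[float] | None = None, match_prob: float = 0.85) -> PSWM:
    """Degenerate inverted-repeat HSE seed (three alternating-orientation AGAAN units)."""
    return consensus_pswm(HSE_SEED, match_prob=match_prob, background=background, name="hse_seed")


def _best_occurrence(window: str, pswm: PSWM) -> tuple[str, float] | None:
    """Best-scoring oriented occurrence of the matrix in one window."""
    width = pswm.width
    if len(window) < width:
        return None
    enc = encode(window.upper())
    tf = _scan_one_strand(enc, pswm._iscores)
    tr = _scan_one_strand(enc, pswm.reverse_complement()._iscores)
    best = None
    for i in range(len(tf)):
        for strand, tot in (("+", tf[i]), ("-", tr[i])):
            if tot <= _NEG // 2:
                continue
            if best is None or tot > best[2]:
                best = (i, strand, int(tot))
    if best is None:
        return None
    i, strand, tot = best
    occ = window[i : i + width].upper()
    if strand == "-":
        occ = revcomp(occ)
    return occ, tot * pswm.score_granularity


def discover_pswm(
    windows: Sequence[str],
    seed_pswm: PSWM | None = None,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.25,
    n_refine: int = 1,
) -> PSWM:
    """Build a motif matrix from peak-flank windows by seeded occurrence extraction.

    Each window is scanned with the seed matrix on both strands, the best
    occurrence per window is kept (oriented to the seed), and a matrix is
    built from the occurrences; ``n_refine`` rescans with the built matrix
    refine it.  Deterministic plumbing in place of EM-based discovery.
    """
    if not windows:
        raise ValueError("at least one window is required")
    model = seed_pswm if seed_pswm is not None else hse_seed_pswm(background)
    for _ in range(n_refine + 1):
        occs = []
        for w in windows:
            best = _best_occurrence(w, model)
            if best is not None:
                occs.append(best[0])
        if not occs:
            raise ValueError("no scoreable occurrence found in any window")
        model = build_pswm(occs, background=background, pseudocount=pseudocount, name="discovered")
    return model


# ----------------------------------------------------------------------
def write_meme(pswm: PSWM, path) -> None:
    """Serialize in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pswm.background)) + "\n\n")
        fh.write(f"MOTIF {pswm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pswm.width} nsites= 20 E= 0\n"
        )
        for row in pswm.probabilities:
            fh.write(" " + "  ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path) -> PSWM:
    """Read the first motif from a MEME minimal format file."""
    rows: list[list[float]] = []
    bg = np.full(4, 0.25)
    name = "motif"
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            parts = next(lines).split()
            bg = np.array([float(parts[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            width = int(line.split("w=")[1].split()[0])
            for _ in range(width):
                rows.append([float(x) for x in next(lines).split()])
            break
    if width is None:
        raise ValueError(f"no motif found in {path}")
    return PSWM(np.array(rows), bg, name=name)
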