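"""Synthetic genomes, tag libraries, and chromatin tracks with known ground truth.

The generator emulates the structure of a knockdown-controlled ChIP-seq study
of an inducible factor:

* a random-background genome with planted inverted-repeat HSE motifs in two
  classes — *bound* (each gets a true, knockdown-sensitive peak centered on
  it) and *free* (equally strong motif, no binding) — plus *decoy*
  direct-repeat motifs (three same-orientation AGAAN units) that a correct
  scanner must not call;
* five tag libraries (experimental NHS/HS, knockdown NHS/HS, pre-immune) with
  Poisson background and strand-asymmetric peak tags, where knockdown
  divides true-peak enrichment by a configurable depletion factor (default
  40, the depletion measured for the factor in the study conditions) while
  knockdown-resistant false-positive peaks keep full enrichment in every IP
  library;
* probe-level chromatin tracks whose enriched regions co-occur with bound vs
  free motifs at configurable class probabilities.

Every generated feature is recorded in :class:`SyntheticTruth`, so each
downstream stage can be scored against exact coordinates.  All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from hsescan.annotation import GeneModel
from hsescan.landscape import ChromatinTrack
from hsescan.motif import BASES, PSWM, consensus_pswm, encode, revcomp
from hsescan.tag_io import TagLibrary

logger = logging.getLogger(__name__)

CHROM = "synth1"

# inverted-repeat HSE seed: three oppositely oriented AGAAN-type 5-bp units
HSE_PLANT_CONSENSUS = "NTTCNNGAANNTTCN"

LIBRARIES = ("exp_nhs", "exp_hs", "kd_nhs", "kd_hs", "preimmune")


@dataclass(frozen=True)
class PlantedMotif:
    position: int  # start of the motif footprint
    strand: str
    klass: str  # bound | free | decoy
    sequence: str

    @property
    def center(self) -> int:
        return self.position + len(self.sequence) // 2

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)


@dataclass(frozen=True)
class TruePeak:
    center: int
    enrichment_fold: float
    kd_resistant: bool


@dataclass
class SyntheticTruth:
    """Complete bookkeeping of everything the generator planted."""

    genome_length: int
    chromosome: str
    planted_motifs: list[PlantedMotif]
    true_peaks: list[TruePeak]
    gene_models: list[GeneModel]
    mark_states: dict[str, set[int]] = field(default_factory=dict)
    seed: int = 0

    def motifs_of_class(self, klass: str) -> list[PlantedMotif]:
        return [m for m in self.planted_motifs if m.klass == klass]

    def validate(self) -> None:
        bound_centers = {m.center for m in self.motifs_of_class("bound")}
        sensitive_centers = {p.center for p in self.true_peaks if not p.kd_resistant}
        if bound_centers != sensitive_centers:
            raise AssertionError("bound motifs and true sensitive peaks do not coincide")
        for p in self.true_peaks:
            if p.kd_resistant and p.center in bound_centers:
                raise AssertionError("kd-resistant peak coincides with a bound motif")
        for m in self.planted_motifs:
            if not (0 <= m.position and m.end <= self.genome_length):
                raise AssertionError("planted motif outside the genome")
        for p in self.true_peaks:
            if not (0 <= p.center < self.genome_length):
                raise AssertionError("peak outside the genome")


# ----------------------------------------------------------------------
def default_motif_model(background: Sequence[float] | None = None) -> PSWM:
    """Sharp planting model for the inverted-repeat HSE (N positions free)."""
    return consensus_pswm(
        HSE_PLANT_CONSENSUS, match_prob=0.94, background=background, name="hse_plant"
    )


def _sample_occurrence(
    model: PSWM, rng: np.random.Generator, max_p: float | None, max_tries: int = 200
) -> str:
    """Sample one occurrence; when ``max_p`` is set, resample until the
    occurrence itself matches the model at p <= max_p (planted sites must meet
    the motif definition the downstream scan uses, or the truth would not be
    recoverable by construction)."""
    for _ in range(max_tries):
        idx = [int(rng.choice(4, p=row)) for row in model.probabilities]
        seq = "".join(BASES[i] for i in idx)
        if max_p is None or model.pvalue(model.score(seq)) <= max_p:
            return seq
    raise RuntimeError(
        f"could not sample an occurrence at p <= {max_p} in {max_tries} tries; "
        "the motif model is too weak for the requested planting threshold"
    )


def _sample_positions(
    n: int, length: int, min_spacing: int, width: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted start positions with pairwise gaps >= min_spacing, away from edges."""
    edge = max(min_spacing, 250)  # keep mappability/profile windows on-genome
    usable = length - 2 * edge - width - (n - 1) * min_spacing
    if n > 0 and usable <= 0:
        raise ValueError(
            f"infeasible packing: {n} sites with spacing {min_spacing} "
            f"do not fit in {length} bases"
        )
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    u = np.sort(rng.choice(usable, size=n, replace=False))
    return u + edge + np.arange(n, dtype=np.int64) * min_spacing


def _generate_genes(length: int, rng: np.random.Generator) -> list[GeneModel]:
    """Alternating gene/gap blocks covering roughly 60% of the genome."""
    genes: list[GeneModel] = []
    pos = int(rng.integers(500, 3000))
    i = 0
    while pos < length - 3000:
        glen = int(rng.integers(2000, 8001))
        end = min(pos + glen, length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(CHROM, pos, end, strand, name=f"gene_{i}"))
        pos = end + int(rng.integers(1000, 6001))
        i += 1
    return genes


def generate_genome(
    length: int,
    n_bound: int,
    n_free: int,
    n_decoy: int,
    motif_model: PSWM | None = None,
    min_spacing: int = 600,
    seed: int = 0,
    n_kd_resistant: int = 0,
    enrichment_fold: float = 40.0,
    base_composition: Sequence[float] | None = None,
    plant_max_p: float | None = 5e-6,
) -> tuple[str, SyntheticTruth]:
    """Generate a background genome with planted motifs and the matching truth.

    Bound- and free-class motifs are sampled from ``motif_model`` (default:
    sharp inverted-repeat HSE); decoys are direct-repeat AGAAN triplets.
    Every bound motif receives one true, knockdown-sensitive peak centered on
    it; ``n_kd_resistant`` knockdown-resistant false-positive peaks are placed
    at motif-free positions.  Placement keeps >= ``min_spacing`` between
    sites; infeasible packing raises instead of silently truncating.
    """
    model = motif_model if motif_model is not None else default_motif_model(base_composition)
    if model.width > min_spacing:
        raise ValueError("motif width must be <= min_spacing")
    rng = np.random.default_rng(seed)
    comp = (
        np.full(4, 0.25) if base_composition is None else np.asarray(base_composition, float)
    )
    if not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must sum to 1")

    n_sites = n_bound + n_free + n_decoy + n_kd_resistant
    positions = _sample_positions(n_sites, length, min_spacing, model.width, rng)
    labels = (
        ["bound"] * n_bound + ["free"] * n_free + ["decoy"] * n_decoy + ["kd_peak"] * n_kd_resistant
    )
    rng.shuffle(labels)

    genome_arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=comp)
    planted: list[PlantedMotif] = []
    peaks: list[TruePeak] = []
    for pos, label in zip(positions, labels):
        pos = int(pos)
        if label == "kd_peak":
            peaks.append(TruePeak(center=pos, enrichment_fold=enrichment_fold, kd_resistant=True))
            continue
        if label == "decoy":
            units = []
            for _ in range(3):
                n_base = BASES[int(rng.integers(4))]
                units.append("AGAA" + n_base)
            seq = "".join(units)
        else:
            seq = _sample_occurrence(model, rng, plant_max_p)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = seq if strand == "+" else revcomp(seq)
        genome_arr[pos : pos + len(seq)] = np.frombuffer(inserted.encode(), dtype="S1")
        planted.append(PlantedMotif(position=pos, strand=strand, klass=label, sequence=seq))
        if label == "bound":
            peaks.append(
                TruePeak(
                    center=pos + len(seq) // 2,
                    enrichment_fold=enrichment_fold,
                    kd_resistant=False,
                )
            )

    genome = genome_arr.tobytes().decode("ascii")
    truth = SyntheticTruth(
        genome_length=length,
        chromosome=CHROM,
        planted_motifs=planted,
        true_peaks=peaks,
        gene_models=_generate_genes(length, rng),
        seed=seed,
    )
    truth.validate()
    return genome, truth


# ----------------------------------------------------------------------
def simulate_tag_libraries(
    truth: SyntheticTruth,
    background_rate: float = 0.05,
    enrichment_folds: Mapping[int, float] | None = None,
    kd_depletion: float = 40.0,
    fragment_sd: float = 20.0,
    shift_mean: float = 75.0,
    signal_window: int = 240,
    library_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> dict[str, TagLibrary]:
    """Simulate the five-tag-library design with Poisson background.

    Background tags are Poisson-uniform at ``background_rate`` per base (or at
    the rate implied by ``library_sizes``).  Each active peak adds
    ``(fold - 1) * rate * signal_window`` expected tags whose 5' ends sit at
    ``center - d`` on the plus strand and ``center + d`` on the minus strand,
    ``d ~ Normal(shift_mean, fragment_sd)`` — exercising the tag-shifting that
    density tracks and summit calling rely on.  Knockdown libraries divide
    true-peak enrichment (fold - 1) by ``kd_depletion``; knockdown-resistant
    peaks keep full enrichment in all four IP libraries; the pre-immune
    library is background only; binding is heat-shock-inducible, so true peaks
    are silent in the NHS libraries.
    """
    if kd_depletion < 1:
        raise ValueError("kd_depletion must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    libs: dict[str, TagLibrary] = {}
    for lib_id in LIBRARIES:
        rate = background_rate
        if library_sizes is not None and lib_id in library_sizes:
            rate = library_sizes[lib_id] / L
        n_bg = int(rng.poisson(rate * L))
        pos = rng.integers(0, L, size=n_bg)
        strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
        all_pos = [pos]
        all_strands = [strands]
        for k, peak in enumerate(truth.true_peaks):
            fold = peak.enrichment_fold
            if enrichment_folds is not None and k in enrichment_folds:
                fold = enrichment_folds[k]
            if fold < 1:
                raise ValueError("enrichment folds must be >= 1")
            if peak.kd_resistant:
                eff = fold if lib_id != "preimmune" else 1.0
            elif lib_id == "exp_hs":
                eff = fold
            elif lib_id == "kd_hs":
                eff = 1.0 + (fold - 1.0) / kd_depletion
            else:  # NHS libraries and pre-immune: inducible binding absent
                eff = 1.0
            lam = (eff - 1.0) * rate * signal_window
            if lam <= 0:
                continue
            n_sig = int(rng.poisson(lam))
            if n_sig == 0:
                continue
            sgn = np.where(rng.random(n_sig) < 0.5, 1, -1)
            d = rng.normal(shift_mean, fragment_sd, size=n_sig)
            p = np.clip(np.rint(peak.center - sgn * d), 0, L - 1).astype(np.int64)
            all_pos.append(p)
            all_strands.append(np.where(sgn > 0, "+", "-"))
        pos = np.concatenate(all_pos)
        strands = np.concatenate(all_strands)
        order = np.argsort(pos, kind="stable")
        lib = TagLibrary(
            library_id=lib_id,
            positions={truth.chromosome: pos[order]},
            strands={truth.chromosome: strands[order]},
            library_total=len(pos),
        )
        if len(pos) == 0:
            logger.warning("simulated library %s is empty", lib_id)
        libs[lib_id] = lib
    return libs


# ----------------------------------------------------------------------
def simulate_chromatin_tracks(
    truth: SyntheticTruth,
    probe_spacing: int = 36,
    assoc_prob_bound: float | Mapping[str, float] = 0.7,
    assoc_prob_free: float | Mapping[str, float] = 0.1,
    signal_fold: Mapping[str, float] | float = 4.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    factors: Sequence[str] | None = None,
    block_halfwidth: int = 250,
    baseline: float = 1.0,
) -> dict[str, ChromatinTrack]:
    """Simulate probe-level chromatin tracks whose enrichment tracks motif class.

    Each bound/free motif is independently flagged enriched with its class
    probability per factor; enriched motifs get a contiguous elevated-probe
    block (``baseline * fold`` + noise) recorded in the track's
    enriched-region list, and ``truth.mark_states`` is updated to match.
    ``signal_fold=1, noise_sd=0`` gives an exactly flat track.
    """
    if probe_spacing < 1:
        raise ValueError("probe_spacing must be >= 1")
    if factors is None:
        factors = sorted(signal_fold) if isinstance(signal_fold, Mapping) else ["mark_A"]
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    probe_pos = np.arange(0, L, probe_spacing, dtype=np.int64)
    tracks: dict[str, ChromatinTrack] = {}
    for factor in factors:
        pb = assoc_prob_bound[factor] if isinstance(assoc_prob_bound, Mapping) else assoc_prob_bound
        pf = assoc_prob_free[factor] if isinstance(assoc_prob_free, Mapping) else assoc_prob_free
        fold = signal_fold[factor] if isinstance(signal_fold, Mapping) else signal_fold
        for prob in (pb, pf):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("association probabilities must lie in [0,1]")
        inten = baseline + (rng.normal(0.0, noise_sd, size=len(probe_pos)) if noise_sd > 0 else 0.0)
        inten = np.asarray(inten, dtype=float)
        if np.isscalar(inten) or inten.ndim == 0:
            inten = np.full(len(probe_pos), float(inten))
        regions: list[tuple[str, int, int]] = []
        enriched: set[int] = set()
        for idx, m in enumerate(truth.planted_motifs):
            if m.klass == "bound":
                prob = pb
            elif m.klass == "free":
                prob = pf
            else:
                continue
            if rng.random() >= prob:
                continue
            enriched.add(idx)
            s, e = m.center - block_halfwidth, m.center + block_halfwidth
            sel = (probe_pos >= s) & (probe_pos < e)
            block = baseline * fold + (
                rng.normal(0.0, noise_sd, size=int(sel.sum())) if noise_sd > 0 else 0.0
            )
            inten[sel] = block
            regions.append((truth.chromosome, max(0, s), min(L, e)))
        tracks[factor] = ChromatinTrack(
            factor,
            {truth.chromosome: probe_pos.copy()},
            {truth.chromosome: inten},
            regions,
        )
        truth.mark_states[factor] = enriched
    return tracks


# ----------------------------------------------------------------------
# Truth and genome serialization (plain text)

def write_fasta(genome: Mapping[str, str] | str, path, line_width: int = 60) -> None:
    if isinstance(genome, str):
        genome = {CHROM: genome}
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_fasta(path) -> dict[str, str]:
    genome: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            elif line and name is not None:
                genome[name].append(line)
    return {k: "".join(v) for k, v in genome.items()}


def write_truth(truth: SyntheticTruth, json_path, motif_tsv_path) -> None:
    payload = {
        "genome_length": truth.genome_length,
        "chromosome": truth.chromosome,
        "seed": truth.seed,
        "true_peaks": [
            {"center": p.center, "enrichment_fold": p.enrichment_fold, "kd_resistant": p.kd_resistant}
            for p in truth.true_peaks
        ],
        "gene_models": [
            {"start": g.start, "end": g.end, "strand": g.strand, "name": g.name}
            for g in truth.gene_models
        ],
        "mark_states": {k: sorted(v) for k, v in truth.mark_states.items()},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(motif_tsv_path, "w") as fh:
        fh.write("chromosome\tposition\tstrand\tclass\tsequence\n")
        for m in truth.planted_motifs:
            fh.write(f"{truth.chromosome}\t{m.position}\t{m.strand}\t{m.klass}\t{m.sequence}\n")
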