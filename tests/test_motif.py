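"""PSWM construction, scoring, exact p-values, scanning, and peak assignment."""

import itertools

import numpy as np
import pytest

from hsescan import motif
from hsescan.motif import (
    PSWM,
    build_pswm,
    consensus_pswm,
    discover_pswm,
    revcomp,
    scan_genome,
    score_pvalue,
    score_sequence,
)


def enumerate_pvalue(pswm: PSWM, score: float) -> float:
    """Independent oracle: P(score >= s) by full 4^W enumeration."""
    total = 0.0
    for seq in itertools.product("ACGT", repeat=pswm.width):
        s = pswm.score("".join(seq))
        if s >= score:
            p = 1.0
            for pos, base in enumerate(seq):
                p *= pswm.background["ACGT".index(base)]
            total += p
    return total


def random_pswm(rng: np.random.Generator, width: int) -> PSWM:
    probs = rng.dirichlet(np.full(4, 0.6), size=width)
    bg = rng.dirichlet(np.full(4, 5.0))
    return PSWM(probs, bg)


class TestBuildPswm:
    def test_identical_occurrences_give_certain_probabilities(self):
        m = build_pswm(["ACGT", "ACGT", "ACGT"], pseudocount=0.0)
        assert np.allclose(m.probabilities[0], [1, 0, 0, 0])
        assert m.logodds[0, 0] == pytest.approx(2.0)  # log2(1/0.25)

    def test_split_position(self):
        m = build_pswm(["AA", "AC"], pseudocount=0.0)
        assert np.allclose(m.probabilities[1], [0.5, 0.5, 0, 0])

    def test_large_pseudocount_pulls_to_background(self):
        bg = np.array([0.1, 0.2, 0.3, 0.4])
        m = build_pswm(["AAAA"], background=bg, pseudocount=1e9)
        assert np.allclose(m.probabilities, np.tile(bg, (4, 1)), atol=1e-6)
        assert np.allclose(m.logodds, 0.0, atol=1e-3)

    def test_n_bases_excluded_from_counts(self):
        m = build_pswm(["AN", "AN", "AC"], pseudocount=0.0)
        assert np.allclose(m.probabilities[1], [0, 1, 0, 0])  # only the C counts

    def test_errors(self):
        with pytest.raises(ValueError):
            build_pswm([])
        with pytest.raises(ValueError, match="AXGT"):
            build_pswm(["AXGT"])
        with pytest.raises(ValueError):
            build_pswm(["AC", "ACG"])


class TestScoring:
    def test_uniform_matrix_scores_zero(self):
        m = PSWM(np.full((5, 4), 0.25))
        assert score_sequence(m, "ACGTA") == pytest.approx(0.0)

    def test_two_position_all_a(self):
        m = build_pswm(["AA"], pseudocount=0.0)
        assert score_sequence(m, "AA") == pytest.approx(4.0)  # 2 x log2(4)

    def test_window_with_n_scores_minus_inf(self):
        m = build_pswm(["AA"], pseudocount=0.25)
        assert score_sequence(m, "AN") == -np.inf

    def test_minus_strand_reverse_complements_first(self):
        m = build_pswm(["AAC"], pseudocount=0.25)
        assert score_sequence(m, "GTT", "-") == pytest.approx(score_sequence(m, "AAC", "+"))

    def test_length_mismatch_raises(self):
        m = build_pswm(["AA"])
        with pytest.raises(ValueError):
            score_sequence(m, "AAA")


class TestPvalue:
    def test_extreme_scores(self):
        m = build_pswm(["ACGT", "AAAA"], pseudocount=0.25)
        assert score_pvalue(m, -np.inf) == 1.0
        assert score_pvalue(m, m.max_score() + 1.0) == 0.0
        assert score_pvalue(m, m.min_score()) == pytest.approx(1.0)

    def test_width2_all_a_quarter_sixteenth(self):
        m = build_pswm(["AA"], pseudocount=0.0)
        # only AA reaches 4.0 bits among the 16 dinucleotides
        assert score_pvalue(m, 4.0) == pytest.approx(1.0 / 16.0, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_enumeration_oracle(self, rng, width):
        m = random_pswm(rng, width)
        for q in (0.95, 0.5, 0.05):
            s = np.quantile([m.score("".join(x)) for x in itertools.product("ACGT", repeat=width)], q)
            assert m.pvalue(float(s)) == pytest.approx(enumerate_pvalue(m, float(s)), abs=1e-9)

    def test_pvalue_nonincreasing_in_score(self, rng):
        m = random_pswm(rng, 6)
        grid = np.linspace(m.min_score() - 1, m.max_score() + 1, 200)
        ps = [m.pvalue(float(s)) for s in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_threshold_is_smallest_significant_score(self, rng):
        m = random_pswm(rng, 5)
        thr = m.score_threshold(1e-2)
        g = m.score_granularity
        assert m.pvalue(thr) <= 1e-2
        assert m.pvalue(thr - g) > 1e-2


class TestScan:
    def test_planted_motifs_all_recovered(self):
        from hsescan import synthetic

        genome, truth = synthetic.generate_genome(
            length=60_000, n_bound=0, n_free=50, n_decoy=0, min_spacing=300, seed=3
        )
        model = synthetic.default_motif_model()
        hits = scan_genome({truth.chromosome: genome}, model, p_threshold=5e-6)
        hit_starts = {h.start for h in hits}
        planted = truth.motifs_of_class("free")
        assert len(hits) >= len(planted)
        assert all(m.position in hit_starts for m in planted)

    def test_empty_plant_gives_only_chance_hits(self):
        from hsescan import synthetic

        genome, truth = synthetic.generate_genome(
            length=50_000, n_bound=0, n_free=0, n_decoy=0, min_spacing=300, seed=4
        )
        model = synthetic.default_motif_model()
        hits = scan_genome({truth.chromosome: genome}, model, p_threshold=5e-6)
        # expectation ~ 2 * L * p = 0.5 chance hits
        assert len(hits) <= 6

    def test_threshold_tightening_nests_hit_sets(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        m = consensus_pswm("ACGTACGT", match_prob=0.7)
        loose = {(h.start, h.strand) for h in scan_genome(genome, m, 1e-2)}
        tight = {(h.start, h.strand) for h in scan_genome(genome, m, 1e-3)}
        assert tight <= loose

    def test_reverse_complement_genome_invariance(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=4000))
        m = consensus_pswm("AACGTG", match_prob=0.8)
        fwd = scan_genome(genome, m, 1e-3)
        rev = scan_genome(revcomp(genome), m, 1e-3)
        L = len(genome)
        flipped = {(L - h.end, "-" if h.strand == "+" else "+") for h in rev}
        assert {(h.start, h.strand) for h in fwd} == flipped

    def test_random_genome_hit_count_near_binomial_expectation(self):
        m = consensus_pswm("ACGTAC", match_prob=0.8)
        p = 1e-3
        thr = m.score_threshold(p)
        p_eff = m.pvalue(thr)  # attained size at the lattice threshold
        n_hits = []
        L = 20_000
        for seed in range(8):
            g = "".join(np.random.default_rng(seed).choice(list("ACGT"), size=L))
            n_hits.append(len(scan_genome(g, m, p)))
        mean_expected = 2 * (L - m.width + 1) * p_eff
        se = np.sqrt(mean_expected / len(n_hits))
        assert abs(np.mean(n_hits) - mean_expected) < 3 * se + 1.0

    def test_short_genome_returns_empty(self):
        m = consensus_pswm("ACGTACGT")
        assert scan_genome("ACG", m, 0.01) == []


class TestAssignment:
    def _peak(self, center):
        from hsescan.peak_filter import Peak

        return Peak("c", center, center - 100, center + 100)

    def _hit(self, start, score=10.0, p=1e-4):
        return motif.MotifHit("c", start, "+", "A" * 15, score, p)

    def test_exact_center_distance_zero(self):
        peak = self._peak(107)  # hit center = start + 7
        hit = self._hit(100)
        assign, dist, _ = motif.assign_peak_motifs([peak], [hit])
        assert assign[peak] is hit
        assert list(dist) == [0]

    def test_nearest_hit_wins(self):
        peak = self._peak(200)
        near = self._hit(200 - 7 + 10)  # center at 210
        far = self._hit(200 - 7 + 30)
        assign, _, _ = motif.assign_peak_motifs([peak], [near, far])
        assert assign[peak] is near

    def test_no_hit_within_halfwidth_is_motif_free(self):
        peak = self._peak(1000)
        assign, dist, _ = motif.assign_peak_motifs([peak], [self._hit(1100)])
        assert assign[peak] is None
        assert len(dist) == 0

    def test_hits_above_p_threshold_ignored(self):
        peak = self._peak(107)
        weak = self._hit(100, p=0.01)
        assign, _, _ = motif.assign_peak_motifs([peak], [weak], p_threshold=1e-3)
        assert assign[peak] is None


class TestDiscovery:
    def test_recovers_planting_matrix_from_flanks(self):
        from hsescan import synthetic

        genome, truth = synthetic.generate_genome(
            length=400_000, n_bound=500, n_free=0, n_decoy=0, min_spacing=500, seed=11,
            plant_max_p=None,  # raw sampling: the learned matrix should approach the model
        )
        windows = [
            genome[m.center - 60 : m.center + 60] for m in truth.motifs_of_class("bound")
        ]
        learned = discover_pswm(windows)
        truthm = synthetic.default_motif_model()
        # total-variation distance per position, averaged
        tv = 0.5 * np.abs(learned.probabilities - truthm.probabilities).sum(axis=1)
        assert tv.mean() < 0.05

    def test_round_trip_meme_format(self, tmp_path, rng):
        m = random_pswm(rng, 7)
        path = tmp_path / "m.meme"
        motif.write_meme(m, path)
        back = motif.read_meme(path)
        assert back.width == 7
        assert np.allclose(back.probabilities, m.probabilities, atol=1e-6)
        assert np.allclose(back.background, m.background, atol=1e-6)
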