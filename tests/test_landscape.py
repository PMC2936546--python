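"""Composite profiles, Fisher association, clustering, intensity correlations."""

import math

import numpy as np
import pytest

from hsescan import landscape, synthetic
from hsescan.landscape import (
    ChromatinTrack,
    cluster_motifs,
    composite_profile,
    enrichment_membership,
    fisher_association,
    fisher_test_table,
    intensity_binding_correlation,
    quartile_intensity,
    window_mean_intensity,
)
from hsescan.motif import MotifHit
from hsescan.tag_io import TagLibrary


def hit(center, chrom="c", strand="+", p=1e-4):
    return MotifHit(chrom, center, strand, "A", 0.0, p)


def flat_track(value=2.0, n=2000, spacing=10, chrom="c", factor="f"):
    pos = np.arange(0, n * spacing, spacing, dtype=np.int64)
    return ChromatinTrack(factor, {chrom: pos}, {chrom: np.full(n, float(value))})


def hypergeom_two_sided(table) -> float:
    """Oracle: tail sum of hypergeometric pmf values <= observed (standard
    1e-7 relative tolerance at ties), computed with exact integer binomials."""
    (a, b), (c, d) = table
    n, r, col = a + b + c + d, a + b, a + c
    denom = math.comb(n, col)
    support = range(max(0, r + col - n), min(r, col) + 1)
    pmf = {k: math.comb(r, k) * math.comb(n - r, col - k) / denom for k in support}
    cut = pmf[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf.values() if p <= cut))


class TestCompositeProfile:
    def test_constant_track_gives_constant_profile(self):
        track = flat_track(2.5)
        prof = composite_profile(track, [hit(5000), hit(9000)], span=1000)
        assert np.allclose(prof.mean_intensity, 2.5)

    def test_central_window_hand_arithmetic(self):
        track = ChromatinTrack(
            "f", {"c": np.array([990, 1000, 1010])}, {"c": np.array([1.0, 2.0, 3.0])}
        )
        prof = composite_profile(track, [hit(1000)], span=100)
        central = prof.mean_intensity[list(prof.offsets).index(0)]
        assert central == pytest.approx(2.0)

    def test_probe_free_windows_omitted_with_count(self):
        track = ChromatinTrack("f", {"c": np.array([1000])}, {"c": np.array([5.0])})
        prof = composite_profile(track, [hit(1000)], span=500)
        i0 = list(prof.offsets).index(0)
        assert prof.n_motifs[i0] == 1
        assert np.isnan(prof.mean_intensity[list(prof.offsets).index(500)])

    def test_planted_block_enrichment_recovered(self, small_dataset):
        _, truth, _, tracks = small_dataset
        track = tracks["mark_A"]
        enriched_idx = truth.mark_states["mark_A"]
        motifs = [
            hit(m.center, truth.chromosome)
            for i, m in enumerate(truth.planted_motifs)
            if i in enriched_idx
        ]
        prof = composite_profile(track, motifs, span=2000)
        i0 = list(prof.offsets).index(0)
        # central window sits inside every enriched block: fold x baseline;
        # far offsets only see neighbouring motifs' blocks occasionally
        edge = prof.mean_intensity[0]
        assert prof.mean_intensity[i0] == pytest.approx(4.0, rel=0.1)
        assert prof.mean_intensity[i0] / edge > 2.5

    def test_permuted_track_is_flat_within_three_se(self, small_dataset):
        _, truth, _, tracks = small_dataset
        rng = np.random.default_rng(5)
        track = tracks["mark_A"]
        chrom = truth.chromosome
        permuted = ChromatinTrack(
            "perm",
            {chrom: track.positions[chrom].copy()},
            {chrom: rng.permutation(track.intensities[chrom])},
        )
        motifs = [hit(m.center, chrom) for m in truth.planted_motifs]
        prof = composite_profile(permuted, motifs, span=2000)
        per_motif_sd = np.std(
            [window_mean_intensity(permuted, m, 100) for m in motifs]
        )
        se = per_motif_sd / np.sqrt(len(motifs))
        grand = np.nanmean(prof.mean_intensity)
        assert np.nanmax(np.abs(prof.mean_intensity - grand)) < 3 * se


class TestWindowMeanIntensity:
    def test_mean_of_probes_in_window(self):
        track = ChromatinTrack(
            "f", {"c": np.array([900, 1000, 1100])}, {"c": np.array([1.0, 2.0, 3.0])}
        )
        assert window_mean_intensity(track, hit(1000), 400) == pytest.approx(2.0)

    def test_no_probes_gives_nan(self):
        track = flat_track(n=10)
        assert np.isnan(window_mean_intensity(track, hit(100_000), 400))


class TestEnrichmentMembership:
    def test_half_open_boundary_convention(self):
        regions = [("c", 100, 200)]
        assert enrichment_membership(hit(100), regions)
        assert enrichment_membership(hit(199), regions)
        assert not enrichment_membership(hit(200), regions)
        assert not enrichment_membership(hit(99), regions)

    def test_empty_region_list(self):
        assert not enrichment_membership(hit(100), [])


class TestFisher:
    def test_eight_of_ten_vs_two_of_ten(self):
        res = fisher_association([True] * 8 + [False] * 2, [True] * 2 + [False] * 8)
        assert res.p_value == pytest.approx(0.023, abs=0.0005)
        assert res.odds_ratio == pytest.approx(16.0)

    def test_identical_proportions_p_one(self):
        res = fisher_association([True] * 5 + [False] * 5, [True] * 5 + [False] * 5)
        assert res.p_value == 1.0

    def test_degenerate_margin_p_one_with_haldane_odds(self):
        res = fisher_association([False] * 10, [False] * 10)
        assert res.p_value == 1.0
        assert res.odds_ratio == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[8, 2], [2, 8]], [[0, 10], [5, 5]], [[3, 0], [0, 4]], [[1, 1], [1, 1]]]
    )
    def test_matches_hypergeometric_oracle(self, table):
        _, p = fisher_test_table(np.array(table))
        assert p == pytest.approx(hypergeom_two_sided(table), abs=1e-12)

    def test_association_recovered_on_synthetic_tracks(self, small_dataset):
        _, truth, _, tracks = small_dataset
        bound = [hit(m.center, truth.chromosome) for m in truth.motifs_of_class("bound")]
        free = [hit(m.center, truth.chromosome) for m in truth.motifs_of_class("free")]
        results = landscape.associate_factors(tracks, bound, free)
        assert all(r["p_value"] < 0.05 for r in results)
        assert all(r["odds_ratio"] > 1 for r in results)
        assert all("p_adjusted_bh" in r for r in results)


class TestClustering:
    def test_two_separated_blobs_partition_perfectly(self, rng):
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(5, 0.1, size=(10, 3))
        X = np.vstack([a, b])
        labels, _ = cluster_motifs(X, k=2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_one_centroid_is_column_mean(self, rng):
        X = rng.normal(size=(8, 2))
        labels, cents = cluster_motifs(X, k=1, seed=0, standardize=False)
        assert np.allclose(cents[0], X.mean(axis=0))
        assert set(labels) == {0}

    def test_k_equals_n_zero_objective(self, rng):
        X = rng.normal(size=(6, 2))
        labels, _ = cluster_motifs(X, k=6, seed=0)
        assert len(set(labels)) == 6

    def test_input_order_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        labels, _ = cluster_motifs(X, k=3, seed=1)
        perm = rng.permutation(30)
        labels_perm, _ = cluster_motifs(X[perm], k=3, seed=1)
        assert np.array_equal(labels[perm], labels_perm)

    def test_k_exceeding_n_raises(self):
        with pytest.raises(ValueError):
            cluster_motifs(np.zeros((3, 2)), k=5)

    def test_missing_values_imputed(self, rng):
        X = rng.normal(size=(12, 3))
        X[0, 1] = np.nan
        labels, _ = cluster_motifs(X, k=2, seed=0)
        assert len(labels) == 12


class TestIntensityBindingCorrelation:
    def _lib_with_counts(self, centers, counts, chrom="c"):
        pos = np.concatenate([np.full(n, c) for c, n in zip(centers, counts)])
        pos.sort()
        return TagLibrary("hsf", {chrom: pos}, {chrom: np.array(["+"] * len(pos))}, 10_000)

    def test_exact_linear_relation_gives_r_one(self):
        centers = [1000, 3000, 5000, 7000]
        counts = [10, 20, 30, 40]
        lib = self._lib_with_counts(centers, counts)
        pos = np.array(centers, dtype=np.int64)
        track = ChromatinTrack("f", {"c": pos}, {"c": np.array(counts, dtype=float)})
        r, p = intensity_binding_correlation(track, [hit(c) for c in centers], lib)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_antilinear_gives_r_minus_one(self):
        centers = [1000, 3000, 5000, 7000]
        counts = [40, 30, 20, 10]
        lib = self._lib_with_counts(centers, counts)
        pos = np.array(centers, dtype=np.int64)
        track = ChromatinTrack("f", {"c": pos}, {"c": np.array([1.0, 2.0, 3.0, 4.0])})
        r, _ = intensity_binding_correlation(track, [hit(c) for c in centers], lib)
        assert r == pytest.approx(-1.0)

    def test_independent_intensities_calibrated_type_one_error(self):
        # t-distribution oracle: |r| exceeds the 5% critical value in ~5% of seeds
        n = 100
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            centers = (np.arange(n) + 1) * 1000
            counts = rng.poisson(20, size=n) + 1
            lib = self._lib_with_counts(centers, counts)
            track = ChromatinTrack(
                "f", {"c": centers.astype(np.int64)}, {"c": rng.normal(size=n)}
            )
            _, p = intensity_binding_correlation(track, [hit(int(c)) for c in centers], lib)
            rejections += p < 0.05
        assert 1 <= rejections <= 11  # 5 +/- 3 sd of Binomial(100, 0.05)

    def test_zero_variance_raises(self):
        centers = [1000, 3000, 5000]
        lib = self._lib_with_counts(centers, [10, 10, 10])
        track = flat_track()
        with pytest.raises(ValueError):
            intensity_binding_correlation(track, [hit(c) for c in centers], lib)


class TestQuartileIntensity:
    def _lib(self, centers, counts):
        pos = np.concatenate([np.full(n, c) for c, n in zip(centers, counts)])
        pos.sort()
        return TagLibrary("hsf", {"c": pos}, {"c": np.array(["+"] * len(pos))}, 10_000_000)

    def test_equal_pvalues_single_group(self):
        centers = [1000, 3000, 5000, 7000]
        lib = self._lib(centers, [5, 5, 5, 5])
        groups = quartile_intensity([hit(c, p=1e-4) for c in centers], lib)
        assert list(groups) == ["all"]

    def test_four_quartiles_by_pvalue(self):
        centers = [1000, 3000, 5000, 7000, 9000, 11000, 13000, 15000]
        lib = self._lib(centers, [1] * 8)
        motifs = [hit(c, p=10.0 ** -(i + 1)) for i, c in enumerate(centers)]
        groups = quartile_intensity(motifs, lib)
        assert len(groups) == 4
        assert sum(len(v) for v in groups.values()) == 8

    def test_shared_window_splits_counts(self):
        # two motifs 100 bases apart share each other's 240-base windows
        lib = self._lib([1000, 1100], [10, 10])
        motifs = [hit(1000, p=1e-3), hit(1100, p=1e-4), hit(9000, p=1e-5), hit(12000, p=1e-6)]
        groups = quartile_intensity(motifs, lib)
        vals = np.concatenate(list(groups.values()))
        # each of the two sharing motifs sees 20 raw tags over 2 motifs -> 10 each
        assert np.isclose(sorted(vals)[-1], 20 * 1e7 / 1e7 / 2)

    def test_counts_independent_of_pvalue_have_similar_quartiles(self, rng):
        centers = (np.arange(40) + 1) * 1000
        counts = rng.poisson(30, size=40)
        lib = self._lib(centers, counts)
        motifs = [hit(int(c), p=float(p)) for c, p in zip(centers, rng.uniform(1e-8, 1e-3, 40))]
        groups = quartile_intensity(motifs, lib)
        medians = [np.median(v) for v in groups.values()]
        # permutation-style check: spread of quartile medians stays within the
        # Poisson sampling scale
        assert max(medians) - min(medians) < 4 * np.sqrt(30) * 1e7 / 1e7
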