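"""Circular-shift machinery, rank P-values, and the two permutation tests."""

import numpy as np
import pytest

from syntad.core_io import Genome, GenomicInterval, Track
from syntad.enrichment import (
    bp_overlap_enrichment,
    circular_shift,
    point_enrichment,
    rank_pvalue,
    shift_points,
)
from tests.conftest import coverage_mask, random_toy_track

GENOME = Genome.from_lengths({"chr1": 1000})


class TestCircularShift:
    def test_full_rotation_is_identity(self):
        track = Track("t", [GenomicInterval("chr1", 100, 200)])
        out = circular_shift(track, GENOME, {"chr1": 1000})
        assert out.intervals == track.intervals

    def test_wrap_around_relocates_interval(self):
        track = Track("t", [GenomicInterval("chr1", 950, 1000)])
        out = circular_shift(track, GENOME, {"chr1": 100})
        assert [(i.start, i.end) for i in out] == [(50, 100)]  # width conserved

    def test_straddling_interval_splits_into_two_pieces(self):
        track = Track("t", [GenomicInterval("chr1", 950, 990)])
        out = circular_shift(track, GENOME, {"chr1": 30})
        assert sorted((i.start, i.end) for i in out) == [(0, 20), (980, 1000)]

    def test_offset_out_of_range_rejected(self):
        track = Track("t", [GenomicInterval("chr1", 0, 10)])
        for bad in (0, 1001, -5):
            with pytest.raises(ValueError):
                circular_shift(track, GENOME, {"chr1": bad})

    def test_matches_per_base_rotation_oracle(self):
        rng = np.random.default_rng(11)
        genome = Genome.from_lengths({"chr1": 500, "chr2": 300})
        for _ in range(25):
            track = random_toy_track(rng, genome)
            offsets = {c: int(rng.integers(1, n + 1)) for c, n in genome.chroms}
            shifted = circular_shift(track, genome, offsets)
            before = coverage_mask(track, genome)
            after = coverage_mask(shifted, genome)
            for chrom, n in genome.chroms:
                assert np.array_equal(np.roll(before[chrom], offsets[chrom]), after[chrom])

    def test_conserves_covered_bp_per_chromosome(self):
        rng = np.random.default_rng(12)
        genome = Genome.from_lengths({"chr1": 800, "chr2": 600})
        track = random_toy_track(rng, genome, 8)
        for _ in range(50):
            offsets = {c: int(rng.integers(1, n + 1)) for c, n in genome.chroms}
            shifted = circular_shift(track, genome, offsets)
            assert shifted.covered_bp_by_chrom() == track.covered_bp_by_chrom()


class TestShiftPoints:
    @pytest.mark.parametrize("pos,m,expected", [(10, 5, 15), (99, 5, 4), (0, 100, 0)])
    def test_modular_arithmetic(self, pos, m, expected):
        genome = Genome.from_lengths({"chr1": 100})
        out = shift_points({"chr1": np.array([pos])}, genome, {"chr1": m})
        assert out["chr1"].tolist() == [expected]

    def test_count_conserved(self):
        genome = Genome.from_lengths({"chr1": 100})
        pos = np.array([0, 10, 55, 99])
        out = shift_points({"chr1": pos}, genome, {"chr1": 73})
        assert len(out["chr1"]) == 4


class TestRankPvalue:
    def test_n_above_all_m_gives_resolution_bound(self):
        m = np.arange(10_000)
        r, p, label = rank_pvalue(10_001, m)
        assert r == 1 and label == "<0.0001"

    def test_tie_with_single_largest_m(self):
        m = np.concatenate([np.zeros(9_999), [5.0]])
        r, p, label = rank_pvalue(5.0, m)
        assert r == 2 and p == pytest.approx(2 / 10_001)

    def test_n_below_all_m_gives_p_one(self):
        m = np.arange(1, 10_001)
        r, p, _ = rank_pvalue(0, m)
        assert p == pytest.approx(1.0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            rank_pvalue(1.0, np.array([]))


class TestBpOverlapEnrichment:
    def test_signal_equal_to_regions_is_enriched(self):
        genome = Genome.from_lengths({"chr1": 100_000})
        regions = Track("r", [GenomicInterval("chr1", 1_000, 2_000)])
        res = bp_overlap_enrichment(regions, regions, genome, n_perm=2_000, seed=0)
        assert res.n == 1_000 and res.enriched and res.fold_change > 5

    def test_empty_regions_degenerate(self):
        genome = Genome.from_lengths({"chr1": 1_000})
        signal = Track("s", [GenomicInterval("chr1", 0, 100)])
        with pytest.warns(UserWarning):
            res = bp_overlap_enrichment(signal, Track("r", []), genome, n_perm=10, seed=0)
        assert res.n == 0 and not res.enriched

    def test_reproducible_for_fixed_seed(self):
        genome = Genome.from_lengths({"chr1": 10_000, "chr2": 8_000})
        rng = np.random.default_rng(4)
        signal = random_toy_track(rng, genome, 6)
        regions = random_toy_track(rng, genome, 6)
        a = bp_overlap_enrichment(signal, regions, genome, n_perm=500, seed=99)
        b = bp_overlap_enrichment(signal, regions, genome, n_perm=500, seed=99)
        assert np.array_equal(a.m_values, b.m_values)
        assert (a.n, a.fold_change, a.rank, a.enriched) == (b.n, b.fold_change, b.rank, b.enriched)

    def test_permuted_statistic_matches_materialised_shift(self):
        """The vectorised m computation equals overlap after an explicit shift."""
        from syntad.core_io import overlap_bp
        from syntad.enrichment import _CoverageIndex, _shifted_overlap

        genome = Genome.from_lengths({"chr1": 700})
        rng = np.random.default_rng(21)
        for _ in range(20):
            signal = random_toy_track(rng, genome, 4)
            regions = random_toy_track(rng, genome, 4)
            m = int(rng.integers(1, 701))
            cov = _CoverageIndex(signal, genome)
            starts, ends = regions.flattened().by_chrom()["chr1"]
            fast = _shifted_overlap(cov, "chr1", starts, ends - starts, np.array([m]))[0]
            slow = overlap_bp(signal, circular_shift(regions.flattened(), genome, {"chr1": m}))
            assert fast == slow


class TestPointEnrichment:
    def test_all_points_in_sparse_regions_is_enriched(self):
        genome = Genome.from_lengths({"chr1": 100_000})
        regions = Track("r", [GenomicInterval("chr1", 500, 1_500)])  # 1% of genome
        points = {"chr1": np.arange(600, 1_400, 40)}
        res = point_enrichment(points, regions, genome, n_perm=2_000, seed=1)
        assert res.n == len(points["chr1"]) and res.enriched

    def test_whole_genome_regions_give_fold_one(self):
        genome = Genome.from_lengths({"chr1": 10_000})
        regions = Track("r", [GenomicInterval("chr1", 0, 10_000)])
        points = {"chr1": np.array([5, 500, 5_000])}
        res = point_enrichment(points, regions, genome, n_perm=200, seed=2)
        assert res.fold_change == pytest.approx(1.0)
        assert not res.enriched

    def test_duplicate_positions_counted_once(self):
        genome = Genome.from_lengths({"chr1": 10_000})
        regions = Track("r", [GenomicInterval("chr1", 0, 1_000)])
        points = {"chr1": np.array([10, 10, 10, 2_000])}
        res = point_enrichment(points, regions, genome, n_perm=100, seed=3)
        assert res.n == 1

    def test_null_mean_tracks_region_coverage_fraction(self):
        # with regions occupying fraction q, E[m] -> q * n_points
        genome = Genome.from_lengths({"chr1": 100_000})
        regions = Track("r", [GenomicInterval("chr1", 10_000, 30_000)])  # q = 0.2
        rng = np.random.default_rng(6)
        points = {"chr1": rng.integers(0, 100_000, size=200)}
        res = point_enrichment(points, regions, genome, n_perm=3_000, seed=7)
        n_pts = len(np.unique(points["chr1"]))
        frac = float(np.mean(res.m_values)) / n_pts
        # binomial-ish bound on the mean of 3000 permutations
        assert abs(frac - 0.2) < 0.02
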