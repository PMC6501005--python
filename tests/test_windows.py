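import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periscope.genome import GenomeModel
from periscope.windows import (
    PeakSet,
    WindowTrack,
    count_peaks_in_windows,
    enrichment_ratio,
    tile_windows,
    window_correlation,
)


class TestTileWindows:
    def test_toy_genome_three_windows(self, toy_genome):
        grid = tile_windows(toy_genome)
        expected = [(0, 1_000_000), (1_000_000, 2_000_000), (2_000_000, 2_500_000)]
        assert list(zip(grid.df["start"], grid.df["end"])) == expected

    def test_exact_multiple_single_window(self):
        grid = tile_windows(GenomeModel.from_dict({"chrA": 1_000_000}))
        assert grid.n_windows == 1

    def test_hg19_chr1_has_250_windows(self):
        grid = tile_windows(GenomeModel.from_dict({"chr1": 249_250_621}))
        assert grid.n_windows == 250

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            tile_windows(GenomeModel(()))


class TestCountPeaks:
    def test_midpoint_assignment(self, toy_genome):
        grid = tile_windows(toy_genome)
        peaks = PeakSet.from_arrays(
            "t", ["chr1", "chr1"], [50, 1_450_000], [150, 1_550_000]
        )
        track = count_peaks_in_windows(peaks, grid)
        assert list(track.counts) == [1, 1, 0]

    def test_boundary_midpoint_goes_to_right_window(self, toy_genome):
        grid = tile_windows(toy_genome)
        peaks = PeakSet.from_arrays("t", ["chr1"], [999_950], [1_000_050])
        track = count_peaks_in_windows(peaks, grid)
        assert list(track.counts) == [0, 1, 0]

    def test_empty_peak_set_all_zero(self, toy_genome):
        grid = tile_windows(toy_genome)
        peaks = PeakSet("t", pd.DataFrame({"chrom": [], "start": [], "end": []}))
        assert count_peaks_in_windows(peaks, grid).counts.sum() == 0

    def test_unknown_chromosome_rejected(self, toy_genome):
        grid = tile_windows(toy_genome)
        peaks = PeakSet.from_arrays("t", ["chrX"], [0], [100])
        with pytest.raises(ValueError, match="chrX"):
            count_peaks_in_windows(peaks, grid)

    def test_overlap_assignment_counts_spanning_peak_twice(self, toy_genome):
        grid = tile_windows(toy_genome)
        peaks = PeakSet.from_arrays("t", ["chr1"], [999_000], [1_001_000])
        track = count_peaks_in_windows(peaks, grid, assignment="overlap")
        assert list(track.counts) == [1, 1, 0]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2_499_000), st.integers(1, 5_000)),
                    max_size=60))
    def test_midpoint_counting_conserves_total(self, intervals):
        """Window counts must sum to the number of peaks for any input."""
        grid = tile_windows(GenomeModel.from_dict({"chr1": 2_500_000}))
        starts = [s for s, _ in intervals]
        ends = [min(s + l, 2_500_000) for s, l in intervals]
        peaks = PeakSet.from_arrays("t", ["chr1"] * len(intervals), starts, ends)
        track = count_peaks_in_windows(peaks, grid)
        assert track.counts.sum() == len(peaks)


class TestEnrichmentRatio:
    def _track(self, genome, counts):
        grid = tile_windows(genome)
        return WindowTrack("t", grid, np.array(counts))

    def test_ratio_and_flags(self, toy_genome):
        track = enrichment_ratio(self._track(toy_genome, [6, 3, 0]))
        np.testing.assert_allclose(track.expected, [3, 3, 3])
        np.testing.assert_allclose(track.ratio, [2, 1, 0])
        assert list(track.flag) == [True, False, False]

    def test_uniform_counts_ratio_exactly_one(self, toy_genome):
        track = enrichment_ratio(self._track(toy_genome, [4, 4, 4]))
        np.testing.assert_array_equal(track.ratio, [1.0, 1.0, 1.0])
        assert not track.flag.any()

    def test_expectation_is_per_chromosome(self, two_chrom_genome):
        track = enrichment_ratio(self._track(two_chrom_genome, [4, 0, 0, 4]))
        np.testing.assert_allclose(track.expected, [2, 2, 2, 2])
        np.testing.assert_allclose(track.ratio, [2, 0, 0, 2])

    def test_zero_total_chromosome_undefined_not_flagged(self, two_chrom_genome):
        track = enrichment_ratio(self._track(two_chrom_genome, [3, 5, 0, 0]))
        assert np.isnan(track.ratio[2:]).all()
        assert not track.flag[2:].any()

    def test_mean_ratio_per_chromosome_is_one(self, two_chrom_genome):
        rng = np.random.default_rng(0)
        track = enrichment_ratio(self._track(two_chrom_genome, rng.poisson(9, 4) + 1))
        df = track.to_frame()
        for _, sub in df.groupby("chrom"):
            assert abs(sub["ratio"].mean() - 1.0) < 1e-9


class TestWindowCorrelation:
    def _ratio_tracks(self, n=50, seed=0, identical=False):
        genome = GenomeModel.from_dict({"chr1": n * 1_000_000})
        grid = tile_windows(genome)
        rng = np.random.default_rng(seed)
        # distinct values so only the identity permutation reproduces r = 1
        counts_a = np.argsort(rng.random(n)) + 1
        counts_b = counts_a if identical else rng.permutation(counts_a)
        ta = enrichment_ratio(WindowTrack("a", grid, counts_a))
        tb = enrichment_ratio(WindowTrack("b", grid, counts_b))
        return ta, tb

    def test_identical_tracks_r_one_minimal_p(self):
        ta, tb = self._ratio_tracks(identical=True)
        res = window_correlation(ta, tb, n_permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_pearson_matches_scipy(self):
        from scipy import stats

        ta, tb = self._ratio_tracks(seed=3)
        res = window_correlation(ta, tb, method="pearson", n_permutations=99, seed=0)
        expected = stats.pearsonr(ta.ratio, tb.ratio).statistic
        assert res.r == pytest.approx(expected)

    def test_spearman_matches_scipy(self):
        from scipy import stats

        ta, tb = self._ratio_tracks(seed=4)
        res = window_correlation(ta, tb, method="spearman", n_permutations=99, seed=0)
        expected = stats.spearmanr(ta.ratio, tb.ratio).statistic
        assert res.r == pytest.approx(expected)

    def test_zero_variance_track_rejected(self):
        genome = GenomeModel.from_dict({"chr1": 20_000_000})
        grid = tile_windows(genome)
        flat = enrichment_ratio(WindowTrack("a", grid, np.full(20, 5)))
        vary = enrichment_ratio(WindowTrack("b", grid, np.arange(1, 21)))
        with pytest.raises(ValueError, match="degenerate"):
            window_correlation(flat, vary, n_permutations=9, seed=0)

    def test_too_few_windows_rejected(self):
        genome = GenomeModel.from_dict({"chr1": 5_000_000})
        grid = tile_windows(genome)
        a = enrichment_ratio(WindowTrack("a", grid, np.arange(1, 6)))
        b = enrichment_ratio(WindowTrack("b", grid, np.arange(5, 0, -1)))
        with pytest.raises(ValueError, match=">= 10"):
            window_correlation(a, b, n_permutations=9, seed=0)

    def test_per_chromosome_correlations_reported(self):
        genome = GenomeModel.from_dict({"chr1": 20_000_000, "chr2": 20_000_000})
        grid = tile_windows(genome)
        rng = np.random.default_rng(7)
        a = enrichment_ratio(WindowTrack("a", grid, rng.poisson(10, 40) + 1))
        b = enrichment_ratio(WindowTrack("b", grid, rng.poisson(10, 40) + 1))
        res = window_correlation(a, b, n_permutations=99, seed=0, per_chromosome=True)
        assert set(res.per_chromosome["chrom"]) == {"chr1", "chr2"}

    def test_p_value_in_unit_interval(self):
        ta, tb = self._ratio_tracks(seed=8)
        res = window_correlation(ta, tb, n_permutations=199, seed=2)
        assert 0 < res.p_value <= 1
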