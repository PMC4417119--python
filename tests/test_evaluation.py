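"""Down-sampling, bin matching, concordance, FN simulation and MAPD."""

import numpy as np
import pandas as pd
import pytest

from scnv.binning import MappabilityTrack, compute_variable_bins
from scnv.counting import RatioProfile, reads_frame
from scnv.evaluation import (FNDesign, breakpoint_concordance, cn_concordance,
                             downsample_reads, false_positive_fraction,
                             mapd_metrics, match_bins, pairwise_mad,
                             simulate_false_negatives)
from conftest import make_bins


class TestDownsample:
    def test_full_sample_is_identity(self, rng):
        reads = reads_frame([("chr1", p, "+") for p in rng.integers(0, 100, 50)])
        out = downsample_reads(reads, 50, seed=1)
        pd.testing.assert_frame_equal(out, reads.reset_index(drop=True))

    def test_same_seed_same_sample(self, rng):
        reads = reads_frame([("chr1", p, "+") for p in range(1000)])
        a = downsample_reads(reads, 300, seed=9)
        b = downsample_reads(reads, 300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_uniformity_binomial_bounds(self):
        reads = reads_frame([("chr1", p, "+") for p in range(10_000)])
        out = downsample_reads(reads, 5_000, seed=3)
        left = (out["pos"] < 5_000).sum()
        # expected 2500, sd = sqrt(n*p*q) ~ 35; 4 sigma
        assert abs(left - 2500) < 4 * 35 * 2

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            downsample_reads(reads_frame([("chr1", 1, "+")]), 2)


class TestMatchBins:
    def test_nested_bins(self):
        small = make_bins({"chr1": 10}, bin_span=10)
        large = make_bins({"chr1": 2}, bin_span=50)
        match = match_bins(small, large)
        assert np.array_equal(match, [0] * 5 + [1] * 5)

    def test_straddling_bin_goes_to_majority(self):
        import pandas as pd
        from scnv.binning import VariableBinning

        small = VariableBinning(pd.DataFrame({
            "chrom": "chr1", "start": [0, 30], "end": [30, 100],
            "mappable_count": 10, "gc": np.nan, "bad": False}))
        large = make_bins({"chr1": 2}, bin_span=50)
        # second small bin overlaps large bins 20/50 -> large bin 1
        assert np.array_equal(match_bins(small, large), [0, 1])

    def test_matches_all_pairs_oracle(self, rng):
        def random_partition(total, n):
            cuts = np.sort(rng.choice(np.arange(1, total), n - 1, replace=False))
            bounds = np.r_[0, cuts, total]
            import pandas as pd
            from scnv.binning import VariableBinning

            return VariableBinning(pd.DataFrame({
                "chrom": "chr1", "start": bounds[:-1], "end": bounds[1:],
                "mappable_count": 1, "gc": np.nan, "bad": False}))

        small = random_partition(500, 40)
        large = random_partition(500, 7)
        match = match_bins(small, large)
        for gi in range(small.n_bins):
            s, e = small.df.start[gi], small.df.end[gi]
            overlaps = [max(0, min(e, le) - max(s, ls))
                        for ls, le in zip(large.df.start, large.df.end)]
            assert match[gi] == int(np.argmax(overlaps))

    def test_disjoint_chromosomes_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            match_bins(make_bins({"chr1": 4}), make_bins({"chr2": 4}))


class TestCNConcordance:
    def test_identical_profiles(self):
        cn = np.full(100, 2.0)
        assert cn_concordance(cn, cn, np.arange(100)) == 1.0

    def test_hand_count(self):
        ref = np.full(1000, 2.0)
        test = ref.copy()
        test[:10] = 3
        assert cn_concordance(ref, test, np.arange(1000)) == pytest.approx(0.99)

    def test_masked_bins_excluded(self):
        ref = np.array([2.0, np.nan, 3.0, 2.0])
        test = np.array([2.0, 2.0, np.nan, 3.0])
        # only bins 0 and 3 compared -> 1 of 2 agree
        assert cn_concordance(ref, test, np.arange(4)) == 0.5

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError):
            cn_concordance(np.array([np.nan]), np.array([2.0]), np.array([0]))


class TestBreakpointConcordance:
    def test_identical(self):
        bp = np.array([10, 40, 70, 90])
        assert breakpoint_concordance(bp, bp, tol_bins=0) == 1.0

    def test_missing_one_of_four(self):
        ref = np.array([10, 40, 70, 90])
        assert breakpoint_concordance(ref, np.array([10, 40, 90]),
                                      tol_bins=0) == 0.75

    def test_shift_by_one_bin(self):
        ref = np.array([10, 40, 70])
        shifted = ref + 1
        assert breakpoint_concordance(ref, shifted, tol_bins=1) == 1.0
        assert breakpoint_concordance(ref, shifted, tol_bins=0) == 0.0

    def test_mapping_through_match(self):
        ref = np.array([10])
        match = np.full(20, 0)
        match[10:] = 5
        assert breakpoint_concordance(ref, np.array([5]), match, tol_bins=0) == 1.0

    def test_no_reference_breakpoints_is_missing(self):
        with pytest.warns(UserWarning, match="no breakpoints"):
            out = breakpoint_concordance(np.array([], dtype=int), np.array([3]))
        assert np.isnan(out)


class TestFalsePositive:
    def test_conforming(self):
        profiles = [np.full(100, 2.0)] * 5
        assert false_positive_fraction(profiles, np.full(100, 2.0)) == 0.0

    def test_hand_count(self):
        profiles = [np.full(100, 2.0) for _ in range(10)]
        profiles[4][17] = 3
        assert false_positive_fraction(profiles, np.full(100, 2.0)) == \
            pytest.approx(0.001)


class TestFNSimulation:
    def _cells_bins(self, noise, rng, n_bins=200):
        bins = make_bins({"chr1": n_bins // 2, "chr2": n_bins // 2})
        cells = [RatioProfile(f"c{i}", 1.0 + rng.normal(0, noise, n_bins))
                 for i in range(3)]
        return cells, bins

    def test_noiseless_cells_have_zero_fn(self, rng):
        cells, bins = self._cells_bins(0.0, rng)
        design = FNDesign(lengths=(5, 9), n_insertions=10, seed=4)
        out = simulate_false_negatives(cells, bins, design, n_perm=200)
        assert (out["fn_rate"] == 0.0).all()

    def test_even_length_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            FNDesign(lengths=(4,))

    def test_no_eligible_placement_errors(self, rng):
        cells, bins = self._cells_bins(0.1, rng, n_bins=8)
        with pytest.raises(ValueError, match="eligible"):
            simulate_false_negatives(cells, bins,
                                     FNDesign(lengths=(13,), n_insertions=1))

    def test_insertion_transform_scales_deviations(self):
        from scnv.evaluation import _insert_segment

        r = np.array([1.0, 1.2, 0.8])
        cn1 = _insert_segment(r, 1)
        # deviations of 0.5*r from 0.5 increased by sqrt(2)
        assert np.allclose(cn1, 0.5 + np.sqrt(2) * (0.5 * r - 0.5))
        cn3 = _insert_segment(r, 3)
        assert np.allclose(cn3, 1.5 + (1.5 * r - 1.5) / np.sqrt(1.5))
        with pytest.raises(ValueError):
            _insert_segment(r, 2)


class TestDownsampleConcordance:
    def test_full_resample_reproduces_reference_and_size_ordering(self):
        """Re-calling the complete read set reproduces the reference calls
        exactly; deep subsamples agree at least as well as shallow ones."""
        from scnv.experiments import downsample_concordance_study

        table = downsample_concordance_study(
            reference_reads=120_000,
            sizes={120_000: 1000, 30_000: 400, 10_000: 200},
            replicates=2, seed=3)
        med = table.groupby("reads")["concordance"].median()
        assert med[120_000] == 1.0  # identical reads, identical calls
        assert med[120_000] >= med[10_000] - 1e-9
        assert ((table["concordance"] >= 0) & (table["concordance"] <= 1)).all()


class TestMAPD:
    def test_identical_cells_zero(self):
        R = np.tile(np.linspace(0.5, 1.5, 50), (3, 1))
        cells, groups = mapd_metrics(R, ["g"] * 3, cn_matrix=np.full((3, 50), 2.0))
        assert (cells["mapd_ratio"] == 0).all()
        assert groups["mapd_cn"].iloc[0] == 0.0

    def test_pairwise_mad_matches_brute_force(self, rng):
        a = 1 + rng.normal(0, 0.2, 500)
        b = 1 + rng.normal(0, 0.2, 500)
        d = a - b
        assert pairwise_mad(a, b) == pytest.approx(
            np.median(np.abs(d - np.median(d))))
        # scaled variant applies the 1.4826 normal-consistency factor
        assert pairwise_mad(a, b, scaled=True) == pytest.approx(
            1.4826 * pairwise_mad(a, b), rel=1e-3)

    def test_gaussian_difference_scale(self, rng):
        # difference of two iid N(1, sigma^2) cells: MAD ~ sigma*sqrt(2)*Phi^-1(0.75)
        sigma = 0.2
        a = 1 + rng.normal(0, sigma, 20_000)
        b = 1 + rng.normal(0, sigma, 20_000)
        expected = sigma * np.sqrt(2) * 0.6744898
        assert pairwise_mad(a, b) == pytest.approx(expected, rel=0.05)

    def test_hand_built_cn_matrix(self):
        C = np.array([[2, 2, 2, 2, 2],
                      [2, 2, 2, 2, 3],   # differs from row0 in 1/5
                      [2, 3, 3, 3, 3]])  # differs from row0 in 4/5, row1 3/5
        R = C.astype(float) / 2
        cells, groups = mapd_metrics(R, ["g"] * 3, cn_matrix=C)
        per_cell = cells.set_index("cell")["mapd_cn"]
        assert per_cell["cell0"] == pytest.approx(np.median([0.2, 0.8]))
        assert per_cell["cell1"] == pytest.approx(np.median([0.2, 0.6]))
        # cell MAPDs are 0.5, 0.4, 0.7 -> group median 0.5
        assert groups["mapd_cn"].iloc[0] == pytest.approx(0.5)

    def test_single_cell_group_warns_nan(self):
        R = np.ones((3, 10))
        with pytest.warns(UserWarning, match="single cell"):
            cells, _ = mapd_metrics(R, ["a", "a", "b"])
        assert np.isnan(cells.set_index("cell").loc["cell2", "mapd_ratio"])
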