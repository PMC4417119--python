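"""Demultiplexing, deduplication, bin counting and ratio normalization."""

import io as stdio

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scnv.binning import MappabilityTrack, compute_variable_bins
from scnv.counting import (BinCountProfile, RatioProfile, count_reads_in_bins,
                           deduplicate_reads, demultiplex_fastq,
                           gc_correct_lowess, normalize_counts, reads_frame)
from conftest import make_bins


def fastq_text(reads):
    return "".join(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n"
                   for i, seq in enumerate(reads))


class TestDemultiplex:
    def test_exact_match_assigns_and_trims(self, tmp_path):
        fq = stdio.StringIO(fastq_text(["AAACCCG" + "TTTTGGGG"]))
        counts = demultiplex_fastq(fq, {"AAACCCG": "cellA"}, tmp_path)
        assert counts["cellA"] == 1 and counts["undetermined"] == 0
        out = (tmp_path / "cellA.fastq").read_text().splitlines()
        assert out[1] == "TTTTGGGG"  # barcode bases trimmed

    def test_one_mismatch_goes_to_undetermined(self, tmp_path):
        fq = stdio.StringIO(fastq_text(["AAACCCT" + "TTTT"]))
        counts = demultiplex_fastq(fq, {"AAACCCG": "cellA"}, tmp_path)
        assert counts["cellA"] == 0 and counts["undetermined"] == 1

    def test_counts_match_generated_proportions(self, tmp_path, rng):
        barcodes = {"AAAAAAA": "c1", "CCCCCCC": "c2",
                    "GGGGGGG": "c3", "TTTTTTT": "c4"}
        picks = rng.choice(list(barcodes), size=1000, p=[0.4, 0.3, 0.2, 0.1])
        fq = stdio.StringIO(fastq_text([b + "ACGTACGT" for b in picks]))
        counts = demultiplex_fastq(fq, barcodes, tmp_path)
        for b, cell in barcodes.items():
            assert counts[cell] == (picks == b).sum()
        assert counts.sum() == 1000  # conservation incl. undetermined

    @pytest.mark.parametrize("table, msg", [
        ([("AAACCCG", "a"), ("AAACCCG", "b")], "duplicate"),
        ({"AAACCNG": "a"}, "non-ACGT"),
        ({"AAACCC": "a"}, "7 bases"),
    ])
    def test_invalid_barcode_tables(self, tmp_path, table, msg):
        with pytest.raises(ValueError, match=msg):
            demultiplex_fastq(stdio.StringIO(""), table, tmp_path)


def test_read_sam_filters_nonunique(tmp_path):
    """Unmapped, secondary and low-MAPQ records are excluded."""
    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t101\t30\t10M\t*\t0\t0\tACGTACGTAC\t*\n"      # + strand
        "r2\t16\tchr1\t201\t30\t10M\t*\t0\t0\tACGTACGTAC\t*\n"     # - strand
        "r3\t0\tchr1\t301\t0\t10M\t*\t0\t0\tACGTACGTAC\t*\n"       # MAPQ 0
        "r4\t256\tchr1\t401\t30\t10M\t*\t0\t0\tACGTACGTAC\t*\n"    # secondary
        "r5\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n")             # unmapped
    from scnv.counting import read_sam

    reads = read_sam(sam)
    # SAM is 1-based; positions come back 0-based
    assert list(reads.itertuples(index=False, name=None)) == [
        ("chr1", 100, "+"), ("chr1", 200, "-")]


def test_read_bed_reads(tmp_path):
    bed = tmp_path / "reads.bed"
    bed.write_text("chr1\t10\t11\tr0\t0\t-\nchr2\t5\t6\tr1\t0\t+\n")
    from scnv.counting import read_bed_reads

    reads = read_bed_reads(bed)
    assert list(reads.itertuples(index=False, name=None)) == [
        ("chr1", 10, "-"), ("chr2", 5, "+")]


class TestDeduplicate:
    def test_identical_records_collapse(self):
        reads = reads_frame([("chr1", 10, "+")] * 3)
        assert len(deduplicate_reads(reads)) == 1

    def test_opposite_strands_are_distinct(self):
        reads = reads_frame([("chr1", 10, "+"), ("chr1", 10, "-")])
        assert len(deduplicate_reads(reads)) == 2

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]),
                              st.integers(0, 30),
                              st.sampled_from(["+", "-"])),
                    max_size=60))
    def test_output_size_equals_distinct_keys(self, records):
        out = deduplicate_reads(reads_frame(records))
        assert len(out) == len(set(records))


class TestCountReads:
    def test_all_reads_in_one_bin(self, uniform_bins):
        reads = reads_frame([("chr1", 33, "+")] * 10)
        profile = count_reads_in_bins(reads, uniform_bins)
        expected = np.zeros(10, dtype=int)
        expected[3] = 10
        assert np.array_equal(profile.counts, expected)

    def test_boundary_read_goes_right(self, uniform_bins):
        # position exactly at a shared boundary: half-open => right-hand bin
        profile = count_reads_in_bins(reads_frame([("chr1", 30, "+")]),
                                      uniform_bins)
        assert profile.counts[3] == 1 and profile.counts[2] == 0

    def test_unbinned_reads_dropped_with_conservation(self, uniform_bins):
        reads = reads_frame([("chr1", 5, "+"), ("chr9", 5, "+"),
                             ("chr1", 5000, "+")])
        profile = count_reads_in_bins(reads, uniform_bins)
        assert profile.dropped == 2
        assert profile.total_reads + profile.dropped == 3

    def test_matches_linear_scan_oracle(self, rng):
        bins = make_bins({"chr1": 20, "chr2": 15}, bin_span=7)
        chroms = rng.choice(["chr1", "chr2"], 10_000)
        pos = rng.integers(0, 160, 10_000)
        profile = count_reads_in_bins(
            pd.DataFrame({"chrom": chroms, "pos": pos, "strand": "+"}), bins)
        expected = np.zeros(bins.n_bins, dtype=int)
        table = bins.df
        for c, p in zip(chroms, pos):
            for k in range(len(table)):
                if (table.chrom[k] == c and table.start[k] <= p < table.end[k]):
                    expected[k] += 1
                    break
        assert np.array_equal(profile.counts, expected)

    def test_unsorted_bins_rejected(self):
        import pandas as pd
        from scnv.binning import VariableBinning

        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10, 0],
                           "end": [20, 10], "mappable_count": [10, 10],
                           "gc": np.nan, "bad": False})
        with pytest.raises(ValueError):
            VariableBinning(df)


class TestNormalize:
    def test_flat_counts_give_unit_ratios(self, uniform_bins):
        profile = BinCountProfile("c", np.full(10, 40))
        assert np.allclose(normalize_counts(profile, uniform_bins).ratio, 1.0)

    def test_hand_arithmetic(self):
        bins = make_bins({"chr1": 4})
        out = normalize_counts(BinCountProfile("c", [10, 20, 30, 40]), bins)
        assert np.allclose(out.ratio, [0.4, 0.8, 1.2, 1.6])

    def test_masked_bin_excluded_from_mean(self):
        bins = make_bins({"chr1": 4}).with_bad([False, False, False, True])
        out = normalize_counts(BinCountProfile("c", [10, 20, 30, 40]), bins)
        assert np.allclose(out.ratio[:3], [0.5, 1.0, 1.5])
        assert np.isnan(out.ratio[3])

    def test_unmasked_mean_is_one(self, rng):
        bins = make_bins({"chr1": 200}).with_bad(rng.random(200) < 0.1)
        out = normalize_counts(BinCountProfile("c", rng.poisson(30, 200)), bins)
        assert abs(np.nanmean(out.ratio[~bins.mask]) - 1) < 1e-6

    def test_zero_reads_error(self, uniform_bins):
        with pytest.raises(ValueError, match="zero reads"):
            normalize_counts(BinCountProfile("c", np.zeros(10, int)),
                             uniform_bins)


class TestGCCorrection:
    n = 5000

    def _bins(self, rng):
        gc = rng.uniform(0.3, 0.6, self.n)
        return make_bins({"chr1": self.n}, gc=gc), gc

    def test_null_bias_roughly_identity(self, rng):
        bins, gc = self._bins(rng)
        ratio = RatioProfile("c", 1.0 + rng.normal(0, 0.1, self.n))
        out = gc_correct_lowess(ratio, bins)
        assert np.max(np.abs(out.ratio - ratio.ratio)) < 0.02

    def test_removes_injected_multiplicative_bias(self, rng):
        bins, gc = self._bins(rng)
        flat = 1.0 + rng.normal(0, 0.01, self.n)
        biased = flat * (1 + 0.8 * (gc - 0.4))
        out = gc_correct_lowess(RatioProfile("c", biased), bins)
        assert np.std(biased) / np.std(out.ratio) >= 5
        assert abs(np.corrcoef(out.ratio, gc)[0, 1]) < 0.05
        # near-idempotence
        again = gc_correct_lowess(out, bins)
        assert np.max(np.abs(again.ratio - out.ratio) / out.ratio) < 0.01

    def test_degenerate_gc_returns_input(self, rng, caplog):
        bins = make_bins({"chr1": 50}, gc=np.full(50, 0.5))
        ratio = RatioProfile("c", 1.0 + rng.normal(0, 0.1, 50))
        with caplog.at_level("WARNING"):
            out = gc_correct_lowess(ratio, bins)
        assert np.array_equal(out.ratio, ratio.ratio)
        assert "degenerate" in caplog.text
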