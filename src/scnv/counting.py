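"""From raw reads to normalized, GC-corrected per-bin ratio profiles.

A cell's copy-number signal is carried by the count of deduplicated,
uniquely mapping reads per variable bin.  Counts are mean-normalized per
cell (the genome-wide mean of unmasked bins is scaled to 1, so in a diploid
cell a ratio of 1 corresponds to copy number 2), then corrected for the
multiplicative GC amplification bias of whole-genome amplification using
lowess smoothing of ratio against bin GC fraction.

Read sets are represented as DataFrames with columns ``chrom, pos, strand``
(``pos`` is the 0-based 5' mapped start).  A bin's reads are those whose
start coordinate falls in the bin's half-open span.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .binning import VariableBinning

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "pos", "strand"]
BARCODE_LENGTH = 7


class ReadRecord(NamedTuple):
    """A uniquely mapping single-end read reduced to its mapped start."""

    chrom: str
    pos: int
    strand: str


@dataclass
class BinCountProfile:
    """Per-bin unique deduplicated read counts for one cell."""

    cell_id: str
    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class RatioProfile:
    """Mean-normalized per-bin ratios; masked bins are NaN."""

    cell_id: str
    ratio: np.ndarray
    gc_corrected: bool = False

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)


def reads_frame(records: Iterable[ReadRecord | tuple]) -> pd.DataFrame:
    """Build a read DataFrame from (chrom, pos, strand) records."""
    return pd.DataFrame.from_records(list(records), columns=READ_COLUMNS)


def read_sam(path, min_mapq: int = 1) -> pd.DataFrame:
    """Load uniquely mapping reads from SAM/BAM.

    Unmapped, secondary and supplementary alignments are skipped; a read is
    taken as uniquely mapping when MAPQ >= ``min_mapq``.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            rows.append((aln.reference_name, aln.reference_start,
                         "-" if aln.is_reverse else "+"))
    return reads_frame(rows)


def read_bed_reads(path) -> pd.DataFrame:
    """Load read start positions from a BED file (3 or 6+ columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(np.int64)})
    out["strand"] = df[5] if df.shape[1] >= 6 else "+"
    return out


def _validate_barcodes(barcode_table) -> dict[str, str]:
    if isinstance(barcode_table, Mapping):
        pairs = list(barcode_table.items())
    else:
        pairs = [tuple(p) for p in barcode_table]
    seen: dict[str, str] = {}
    for barcode, cell in pairs:
        barcode = str(barcode).upper()
        if len(barcode) != BARCODE_LENGTH:
            raise ValueError(f"barcode {barcode!r} is not {BARCODE_LENGTH} bases")
        if set(barcode) - set("ACGT"):
            raise ValueError(f"barcode {barcode!r} contains non-ACGT bases")
        if barcode in seen:
            raise ValueError(f"duplicate barcode {barcode!r}")
        seen[barcode] = str(cell)
    return seen


def demultiplex_fastq(fastq, barcode_table, outdir) -> pd.Series:
    """Split a FASTQ stream by inline 7-base barcodes.

    Each read is assigned by *exact* match of its first seven bases against
    the barcode table; the barcode bases are trimmed from the output record.
    Non-matching reads go to ``undetermined.fastq`` untrimmed.  Returns
    per-cell read counts (including ``undetermined``).
    """
    from Bio import SeqIO

    table = _validate_barcodes(barcode_table)
    os.makedirs(outdir, exist_ok=True)
    handles = {cell: open(os.path.join(outdir, f"{cell}.fastq"), "w")
               for cell in dict.fromkeys(table.values())}
    handles["undetermined"] = open(os.path.join(outdir, "undetermined.fastq"), "w")
    counts = {cell: 0 for cell in handles}
    try:
        for rec in SeqIO.parse(fastq, "fastq"):
            barcode = str(rec.seq[:BARCODE_LENGTH]).upper()
            cell = table.get(barcode)
            if cell is None:
                SeqIO.write(rec, handles["undetermined"], "fastq")
                counts["undetermined"] += 1
            else:
                SeqIO.write(rec[BARCODE_LENGTH:], handles[cell], "fastq")
                counts[cell] += 1
    finally:
        for fh in handles.values():
            fh.close()
    return pd.Series(counts, name="reads")


def deduplicate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Remove PCR duplicates: keep one read per (chrom, pos, strand).

    Reads are sorted by the key first, so retention is deterministic (the
    first record in sorted order survives).  Mate information is not part of
    the key (single-end data).
    """
    return (reads.sort_values(READ_COLUMNS, kind="stable")
                 .drop_duplicates(READ_COLUMNS)
                 .reset_index(drop=True))


def count_reads_in_bins(reads: pd.DataFrame, bins: VariableBinning,
                        cell_id: str = "cell") -> BinCountProfile:
    """Count deduplicated unique reads per bin by their 5' start coordinate.

    Reads on unbinned contigs or outside any bin are dropped (and counted in
    the profile's ``dropped`` field), so ``total_reads + dropped`` equals the
    input size.
    """
    idx = bins.assign_bins(reads["chrom"].to_numpy(), reads["pos"].to_numpy())
    dropped = int((idx < 0).sum())
    if dropped:
        logger.info("%s: dropped %d/%d reads outside the binning",
                    cell_id, dropped, len(reads))
    counts = np.bincount(idx[idx >= 0], minlength=bins.n_bins)
    return BinCountProfile(cell_id=cell_id, counts=counts, dropped=dropped)


def normalize_counts(profile: BinCountProfile, bins: VariableBinning) -> RatioProfile:
    """Divide a cell's bin counts by its mean count over unmasked bins.

    Masked (bad) bins become NaN; the mean of the unmasked ratios is exactly
    1 by construction.
    """
    good = ~bins.mask
    total = profile.counts[good].sum()
    if total == 0:
        raise ValueError(f"{profile.cell_id}: zero reads over unmasked bins")
    mean = profile.counts[good].mean()
    ratio = profile.counts / mean
    ratio = np.where(good, ratio, np.nan)
    return RatioProfile(cell_id=profile.cell_id, ratio=ratio)


def gc_correct_lowess(profile: RatioProfile, bins: VariableBinning,
                      span: float = 0.5) -> RatioProfile:
    """Remove the GC amplification bias by lowess smoothing.

    A locally weighted regression of ratio on bin GC fraction is fitted over
    unmasked bins (``span`` is the lowess bandwidth fraction); each ratio is
    divided by its fitted value (the bias is multiplicative) and the profile
    is re-normalized to mean 1.  If the GC range is degenerate the input is
    returned unchanged with a warning.
    """
    gc = bins.gc
    good = ~bins.mask & np.isfinite(profile.ratio) & np.isfinite(gc)
    if not good.any():
        raise ValueError("no usable bins for GC correction")
    if np.ptp(gc[good]) == 0:
        logger.warning("degenerate GC range; returning profile uncorrected")
        return replace(profile, ratio=profile.ratio.copy())
    fitted = _sm_lowess(profile.ratio[good], gc[good], frac=span,
                        return_sorted=False)
    fitted = np.clip(fitted, 1e-6, None)
    corrected = np.full_like(profile.ratio, np.nan)
    corrected[good] = profile.ratio[good] / fitted
    corrected[good] /= corrected[good].mean()
    return RatioProfile(cell_id=profile.cell_id, ratio=corrected,
                        gc_corrected=True)
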