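"""Variable-size genome binning for sparse read-depth copy-number analysis.

Read-depth CNV callers count reads in genomic windows.  With fixed-width
windows the expected count per window varies with local mappability, which
confounds depth with alignability.  The variable-bin ("varbin") partition
instead gives every bin the *same number of uniquely mappable positions*, so
that under a flat copy-number landscape every bin has the same expected count
of uniquely mapping reads.  Bins therefore have variable genomic span: spans
stretch over poorly mappable sequence (e.g. pericentromeric repeats).

All coordinates in this module are 0-based, half-open.

The module also implements "bad bin" detection: some genomic regions show
recurrently and anomalously high read depth across unrelated normal cells
(mostly pericentromeric).  Those bins are flagged with a one-sided upper-tail
outlier test at a per-bin tail probability of 1/N (N = number of bins) and
masked from downstream copy-number analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: chromosome names treated as sex chromosomes by default
DEFAULT_SEX_CHROMS = ("chrX", "chrY", "X", "Y")

BIN_COLUMNS = ["chrom", "start", "end", "mappable_count", "gc", "bad"]


@dataclass(frozen=True)
class MappabilityTrack:
    """Uniquely mappable positions of a genome.

    Parameters
    ----------
    intervals
        Per-chromosome ``(k, 2)`` integer arrays of 0-based half-open
        intervals of uniquely mappable positions; sorted, non-overlapping.
    chrom_lengths
        Chromosome lengths in bp.  Dictionary order defines genome order.
    """

    intervals: Mapping[str, np.ndarray]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")
        for chrom, arr in self.intervals.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"intervals for unknown chromosome {chrom}")
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"intervals for {chrom} must be (k, 2)")
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"empty/inverted interval on {chrom}")
            if np.any(arr[:, 0] < 0) or np.any(arr[:, 1] > self.chrom_lengths[chrom]):
                raise ValueError(f"interval out of bounds on {chrom}")
            if arr.shape[0] > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping or unsorted intervals on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def mappable_count(self, chrom: str) -> int:
        arr = np.asarray(self.intervals.get(chrom, np.empty((0, 2), dtype=int)))
        if arr.size == 0:
            return 0
        return int((arr[:, 1] - arr[:, 0]).sum())

    @property
    def total_mappable(self) -> int:
        return sum(self.mappable_count(c) for c in self.chroms)

    def positions_of_ordinals(self, chrom: str, ordinals: np.ndarray) -> np.ndarray:
        """Genomic position of the i-th mappable position (0-based ordinal)."""
        arr = np.asarray(self.intervals[chrom])
        ordinals = np.asarray(ordinals, dtype=np.int64)
        lens = arr[:, 1] - arr[:, 0]
        cum = np.cumsum(lens)
        if ordinals.size and (ordinals.min() < 0 or ordinals.max() >= cum[-1]):
            raise IndexError(f"mappable ordinal out of range on {chrom}")
        idx = np.searchsorted(cum, ordinals, side="right")
        prev = np.where(idx > 0, cum[idx - 1], 0)
        return arr[idx, 0] + (ordinals - prev)

    @classmethod
    def from_bed(cls, path, chrom_lengths: Mapping[str, int] | None = None) -> "MappabilityTrack":
        """Read uniquely mappable intervals from a 3+ column BED file.

        When ``chrom_lengths`` is omitted, each chromosome's length is taken
        as the end of its last interval.
        """
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        intervals: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
            intervals[str(chrom)] = arr[np.argsort(arr[:, 0], kind="stable")]
        if chrom_lengths is None:
            chrom_lengths = {c: int(a[:, 1].max()) for c, a in intervals.items()}
        return cls(intervals=intervals, chrom_lengths=dict(chrom_lengths))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for start, end in np.asarray(self.intervals.get(chrom, [])).reshape(-1, 2):
                    fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass(frozen=True)
class VariableBinning:
    """An ordered genome partition into variable-span, equal-content bins.

    Wraps a DataFrame with columns ``chrom, start, end, mappable_count, gc,
    bad``.  Bins tile each chromosome contiguously in genome order and never
    span chromosome boundaries.  ``gc`` is NaN until annotated;
    ``bad`` marks bins masked from copy-number analysis.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BIN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"bin table missing columns {missing}")
        for chrom, grp in self.df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if np.any(e <= s):
                raise ValueError(f"empty bin on {chrom}")
            if np.any(s[1:] != e[:-1]):
                raise ValueError(f"bins do not tile {chrom} contiguously")

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True for bad (masked) bins."""
        return self.df["bad"].to_numpy(dtype=bool)

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=float)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Row range of each chromosome (bins are chromosome-contiguous)."""
        out: dict[str, slice] = {}
        codes = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(codes) + 1):
            if i == len(codes) or codes[i] != codes[start]:
                if codes[start] in out:
                    raise ValueError("bin table not chromosome-contiguous")
                out[codes[start]] = slice(start, i)
                start = i
        return out

    def is_autosome(self, sex_chroms=DEFAULT_SEX_CHROMS) -> np.ndarray:
        return ~self.df["chrom"].isin(sex_chroms).to_numpy()

    def with_bad(self, bad: np.ndarray) -> "VariableBinning":
        df = self.df.copy()
        df["bad"] = np.asarray(bad, dtype=bool)
        return VariableBinning(df)

    def assign_bins(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Global bin index containing each (chrom, pos); -1 when unbinned.

        A position belongs to the bin whose half-open span [start, end)
        contains it, so a position exactly at a shared boundary goes to the
        right-hand bin.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(pos.shape, -1, dtype=np.int64)
        slices = self.chrom_slices()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        for c, sl in slices.items():
            sel = chrom == c
            if not sel.any():
                continue
            p = pos[sel]
            idx = np.searchsorted(starts[sl], p, side="right") - 1
            ok = (idx >= 0) & (p < ends[sl][np.clip(idx, 0, sl.stop - sl.start - 1)])
            res = np.where(ok, idx + sl.start, -1)
            out[sel] = res
        return out

    def to_tsv(self, path) -> None:
        """Write a BED-like TSV (0-based, half-open coordinates)."""
        df = self.df.copy()
        df["bad"] = df["bad"].astype(int)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariableBinning":
        df = pd.read_csv(path, sep="\t")
        df["bad"] = df["bad"].astype(bool)
        return cls(df[BIN_COLUMNS])


def compute_variable_bins(track: MappabilityTrack, n_bins: int) -> VariableBinning:
    """Partition the genome into ``n_bins`` bins of equal mappable content.

    The total bin count is apportioned across chromosomes proportionally to
    their uniquely mappable content (largest-remainder rounding, every
    chromosome with mappable content receiving at least one bin).  Within a
    chromosome holding m mappable positions and n bins, every bin receives
    floor(m/n) mappable positions and the division remainder is absorbed by
    the chromosome's last bin.  Bin boundaries fall on the first mappable
    position of each bin, except that the first bin of a chromosome starts at
    0 and the last ends at the chromosome length, so bins tile each
    chromosome exactly.  Chromosomes without any mappable position receive no
    bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts = {c: track.mappable_count(c) for c in track.chroms}
    chroms = [c for c in track.chroms if counts[c] > 0]
    total = sum(counts[c] for c in chroms)
    if total < n_bins:
        detail = ", ".join(f"{c}: {counts[c]}" for c in chroms)
        raise ValueError(
            f"genome has {total} mappable positions ({detail}), fewer than "
            f"{n_bins} bins")

    # largest-remainder apportionment, >=1 bin per chromosome with content
    raw = {c: n_bins * counts[c] / total for c in chroms}
    alloc = {c: int(np.floor(raw[c])) for c in chroms}
    leftovers = sorted(chroms, key=lambda c: (-(raw[c] - alloc[c]), chroms.index(c)))
    for c in leftovers[: n_bins - sum(alloc.values())]:
        alloc[c] += 1
    for c in chroms:
        if alloc[c] == 0:
            donor = max(chroms, key=lambda d: alloc[d])
            if alloc[donor] <= 1:
                raise ValueError("cannot give every chromosome a bin")
            alloc[donor] -= 1
            alloc[c] = 1
    for c in chroms:
        if alloc[c] > counts[c]:
            raise ValueError(
                f"chromosome {c} has {counts[c]} mappable positions, fewer "
                f"than its {alloc[c]} allotted bins")

    rows = []
    for c in chroms:
        m, n = counts[c], alloc[c]
        q, r = divmod(m, n)
        mapp = np.full(n, q, dtype=np.int64)
        mapp[-1] += r
        if n > 1:
            inner = track.positions_of_ordinals(c, np.arange(1, n, dtype=np.int64) * q)
        else:
            inner = np.empty(0, dtype=np.int64)
        starts = np.concatenate([[0], inner])
        ends = np.concatenate([inner, [track.chrom_lengths[c]]])
        rows.append(pd.DataFrame({
            "chrom": c, "start": starts, "end": ends,
            "mappable_count": mapp, "gc": np.nan, "bad": False,
        }))
    return VariableBinning(pd.concat(rows, ignore_index=True))


def _chrom_sequence(genome, chrom: str, end: int) -> str:
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq
    return str(seq[0:end])  # pyfaidx / Bio.Seq style objects


def compute_bin_gc(bins: VariableBinning, genome) -> VariableBinning:
    """Annotate each bin with its GC fraction.

    ``gc = (G+C) / (A+C+G+T)`` over the bin's genomic span; ambiguous bases
    (N etc.) are excluded from the denominator.  ``genome`` maps chromosome
    name to sequence (plain strings or a pyfaidx ``Fasta``).
    """
    df = bins.df.copy()
    gc_out = np.full(len(df), np.nan)
    for chrom, sl in bins.chrom_slices().items():
        chrom_end = int(df["end"].to_numpy()[sl.stop - 1])
        seq = _chrom_sequence(genome, chrom, chrom_end)
        if len(seq) < chrom_end:
            raise ValueError(f"sequence for {chrom} shorter than last bin end")
        b = np.frombuffer(seq[:chrom_end].upper().encode("ascii"), dtype=np.uint8)
        is_gc = ((b == ord("G")) | (b == ord("C"))).astype(np.int64)
        is_acgt = is_gc + ((b == ord("A")) | (b == ord("T"))).astype(np.int64)
        starts = df["start"].to_numpy()[sl]
        gc_counts = np.add.reduceat(is_gc, starts)
        acgt_counts = np.add.reduceat(is_acgt, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            gc_out[sl] = np.where(acgt_counts > 0, gc_counts / acgt_counts, np.nan)
    if np.isnan(gc_out).any():
        logger.warning("%d bins have no unambiguous bases; gc set to NaN",
                       int(np.isnan(gc_out).sum()))
    df["gc"] = gc_out
    return VariableBinning(df)


def identify_bad_bins(
    normal_cell_counts,
    bins: VariableBinning,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> VariableBinning:
    """Flag recurrently over-represented bins from a panel of normal cells.

    Procedure: (1) divide each cell's bin counts by that cell's mean count;
    (2) per chromosome, subtract the mean of that chromosome's normalized
    counts over all cells; (3) estimate mean and SD of the adjusted values
    over autosomal bins; (4) flag bins whose cross-cell mean adjusted value
    exceeds the one-sided upper threshold ``mean + z * SD`` with ``z`` the
    standard-normal quantile at tail probability 1/N.  The test is one-sided
    because the artefact being removed is an accumulation of excess depth.
    Sex chromosomes do not contribute to the mean/SD estimate but remain
    eligible for flagging.

    ``normal_cell_counts`` is a bins x cells matrix (ndarray or DataFrame)
    from at least two cells binned on ``bins``.
    """
    C = np.asarray(normal_cell_counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != bins.n_bins:
        raise ValueError("counts must be a bins x cells matrix")
    if C.shape[1] < 2:
        raise ValueError(
            "bad-bin detection needs >=2 normal cells; a single cell gives "
            "no reliable spread estimate")
    cell_means = C.mean(axis=0, keepdims=True)
    if np.any(cell_means == 0):
        raise ValueError("a cell has zero total counts")
    norm_counts = C / cell_means
    adj = norm_counts.copy()
    for chrom, sl in bins.chrom_slices().items():
        adj[sl] -= norm_counts[sl].mean()
    auto = bins.is_autosome(sex_chroms)
    mu = adj[auto].mean()
    sd = adj[auto].std(ddof=1)
    z = norm.isf(1.0 / bins.n_bins)
    bad = adj.mean(axis=1) > mu + z * sd
    logger.info("flagged %d/%d bad bins (1/N upper-tail threshold)",
                int(bad.sum()), bins.n_bins)
    return bins.with_bad(bad)
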