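"""Validation machinery for sparse single-cell copy-number calls.

Implements the experiments used to characterize the pipeline:

* read down-sampling: draw uniform subsamples of a cell's reads and compare
  copy-number calls at coarser bin resolutions against a deep reference;
* cross-resolution bin matching (each fine bin mapped to the coarse bin of
  maximal genomic overlap) with copy-number and breakpoint concordance;
* false-negative simulation: splice synthetic copy-number 1 and 3 segments
  into normal diploid ratio profiles, re-segment, and check the call at the
  central bin of the inserted segment;
* false-positive accounting against an expected copy-number map;
* MAPD consistency metrics (median absolute pairwise difference) on the
  ratio scale and on the integer-call scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .binning import DEFAULT_SEX_CHROMS, VariableBinning
from .counting import RatioProfile
from .ploidy import round_half_away
from .segmentation import segment_series

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DownsampleDesign:
    """Read totals and replication of a down-sampling experiment.

    The defaults mirror a standard design: subsamples of 2M, 1M and 250K
    reads analyzed at 50K, 20K and 5K bins, 100 replicates each, against a
    6M-read reference at 50K bins.
    """

    sizes: dict[int, int] = field(default_factory=lambda: {
        2_000_000: 50_000, 1_000_000: 20_000, 250_000: 5_000})
    replicates: int = 100
    reference_reads: int = 6_000_000
    reference_bins: int = 50_000
    seed: int = 0


@dataclass(frozen=True)
class FNDesign:
    """Design of the false-negative insertion simulation.

    Deviations of the spliced values scale as under Poisson counting: for
    copy number 1 the ratio is halved and its deviations from 0.5 increase
    by sqrt(2); for copy number 3 the ratio is multiplied by 1.5 and its
    deviations from 1.5 shrink by sqrt(1.5).
    """

    lengths: tuple[int, ...] = (5, 9, 13)
    copy_numbers: tuple[int, ...] = (1, 3)
    n_insertions: int = 1000  # per (copy number, length) combination
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length % 2 == 0 for length in self.lengths):
            raise ValueError("segment lengths must be odd (central bin)")


def downsample_reads(reads: pd.DataFrame, m: int,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Uniform sample of exactly ``m`` reads without replacement (seeded)."""
    if m > len(reads):
        raise ValueError(f"cannot sample {m} from {len(reads)} reads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=m, replace=False))
    return reads.iloc[idx].reset_index(drop=True)


def match_bins(small: VariableBinning, large: VariableBinning) -> np.ndarray:
    """Map each fine-partition bin to the coarse bin of maximal overlap.

    Returns an integer array of length ``small.n_bins`` with global indices
    into ``large``; overlap-length ties go to the earlier coarse bin.
    """
    small_slices = small.chrom_slices()
    large_slices = large.chrom_slices()
    if not set(small_slices) & set(large_slices):
        raise ValueError("partitions share no chromosome")
    out = np.full(small.n_bins, -1, dtype=np.int64)
    s_start = small.df["start"].to_numpy()
    s_end = small.df["end"].to_numpy()
    l_start = large.df["start"].to_numpy()
    l_end = large.df["end"].to_numpy()
    for chrom, ssl in small_slices.items():
        if chrom not in large_slices:
            raise ValueError(f"chromosome {chrom} absent from coarse partition")
        lsl = large_slices[chrom]
        ls, le = l_start[lsl], l_end[lsl]
        for gi in range(ssl.start, ssl.stop):
            lo = np.searchsorted(le, s_start[gi], side="right")
            hi = np.searchsorted(ls, s_end[gi], side="left")
            if hi <= lo:
                continue
            overlaps = (np.minimum(s_end[gi], le[lo:hi])
                        - np.maximum(s_start[gi], ls[lo:hi]))
            out[gi] = lsl.start + lo + int(np.argmax(overlaps))
    if np.any(out < 0):
        raise ValueError("some fine bins have no overlapping coarse bin")
    return out


def _cn_array(profile) -> np.ndarray:
    return np.asarray(getattr(profile, "cn", profile), dtype=float)


def cn_concordance(reference, test, match: np.ndarray) -> float:
    """Fraction of reference bins whose call equals the matched test bin's.

    Bins masked (NaN) in either profile are excluded from numerator and
    denominator.
    """
    ref = _cn_array(reference)
    tst = _cn_array(test)[np.asarray(match)]
    ok = np.isfinite(ref) & np.isfinite(tst)
    if not ok.any():
        raise ValueError("no jointly unmasked bins to compare")
    return float(np.mean(ref[ok] == tst[ok]))


def breakpoint_concordance(reference, test, match: np.ndarray | None = None,
                           tol_bins: int = 1) -> float:
    """Fraction of reference breakpoints recovered by the test profile.

    Reference breakpoints (fine-bin indices) are mapped through ``match``
    onto the test partition; a breakpoint counts as called when a test
    breakpoint lies within ``tol_bins`` coarse bins of the mapped position.
    Returns NaN (with a warning) when the reference has no breakpoints.
    """
    ref_bp = np.asarray(getattr(reference, "breakpoints", reference), dtype=np.int64)
    test_bp = np.asarray(getattr(test, "breakpoints", test), dtype=np.int64)
    if ref_bp.size == 0:
        warnings.warn("reference has no breakpoints; concordance undefined")
        return float("nan")
    mapped = np.asarray(match)[ref_bp] if match is not None else ref_bp
    if test_bp.size == 0:
        return 0.0
    called = [np.min(np.abs(test_bp - m)) <= tol_bins for m in mapped]
    return float(np.mean(called))


def false_positive_fraction(profiles, expected: np.ndarray) -> float:
    """Aggregate fraction of unmasked bins deviating from the expected CN."""
    expected = np.asarray(expected, dtype=float)
    deviant = total = 0
    for profile in profiles:
        cn = _cn_array(profile)
        ok = np.isfinite(cn)
        deviant += int(np.sum(cn[ok] != expected[ok]))
        total += int(ok.sum())
    return deviant / total if total else 0.0


# ---------------------------------------------------------------------------
# false-negative simulation


def _insert_segment(values: np.ndarray, cn: int) -> np.ndarray:
    """Splice a simulated CN segment into normalized diploid ratios."""
    if cn == 1:
        return 0.5 + sqrt(2.0) * (0.5 * values - 0.5)
    if cn == 3:
        return 1.5 + (1.5 * values - 1.5) / sqrt(1.5)
    raise ValueError("only copy numbers 1 and 3 are simulated")


def _eligible_starts(bins: VariableBinning, length: int,
                     exclude: np.ndarray | None,
                     sex_chroms) -> list[tuple[str, int]]:
    good = ~bins.mask & bins.is_autosome(sex_chroms)
    if exclude is not None:
        good &= ~np.asarray(exclude, dtype=bool)
    starts = []
    for chrom, sl in bins.chrom_slices().items():
        g = good[sl]
        # exclude chromosome-terminal bins so segments never touch boundaries
        g[0] = g[-1] = False
        ok = np.ones(len(g) - length + 1, dtype=bool) if len(g) >= length else np.zeros(0, bool)
        for off in range(length):
            ok &= g[off:off + len(ok)]
        starts.extend((chrom, sl.start + int(i)) for i in np.flatnonzero(ok))
    return starts


def simulate_false_negatives(
    cells: list[RatioProfile],
    bins: VariableBinning,
    design: FNDesign = FNDesign(),
    *,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    exclude: np.ndarray | None = None,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> pd.DataFrame:
    """False-negative rates of segment detection by insertion simulation.

    For each (copy number, length) combination, ``design.n_insertions``
    segments are spliced into randomly chosen diploid cells at random runs
    of contiguous autosomal bins that avoid masked bins, the ``exclude``
    mask (e.g. centromeres) and chromosome boundaries.  The affected
    chromosome is re-segmented (segmentation is per-chromosome, so this is
    exact) and the call at the central bin — the doubled, rounded segment
    mean — is compared with the inserted copy number.  Returns a tidy table
    with one row per combination.
    """
    if not cells:
        raise ValueError("need at least one diploid cell")
    slices = bins.chrom_slices()
    rows = []
    for cn in design.copy_numbers:
        for length in design.lengths:
            starts = _eligible_starts(bins, length, exclude, sex_chroms)
            if not starts:
                raise ValueError(f"no eligible placement for length {length}")
            fn = 0
            for it in range(design.n_insertions):
                rng = np.random.default_rng(np.random.SeedSequence(
                    [design.seed & 0x7FFFFFFF, cn, length, it]))
                cell = cells[int(rng.integers(len(cells)))]
                chrom, start = starts[int(rng.integers(len(starts)))]
                sl = slices[chrom]
                good = (~bins.mask & np.isfinite(cell.ratio))[sl]
                x = cell.ratio[sl][good].copy()
                compact = np.cumsum(good) - 1  # global offset -> compact index
                lo = compact[start - sl.start]
                x[lo:lo + length] = _insert_segment(x[lo:lo + length], cn)
                segs = segment_series(
                    x, alpha=alpha, n_perm=n_perm, min_width=min_width,
                    seed=int(rng.integers(2**31)))
                center = lo + length // 2
                mean = next(x[a:b].mean() for a, b in segs if a <= center < b)
                called = int(round_half_away(np.array(2.0 * mean)))
                fn += called != cn
            rows.append({"cn": cn, "length": length,
                         "n": design.n_insertions, "false_negatives": fn,
                         "fn_rate": fn / design.n_insertions})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAPD consistency metrics


def pairwise_mad(a: np.ndarray, b: np.ndarray, scaled: bool = False) -> float:
    """Median absolute deviation of the per-bin difference of two cells.

    Unscaled by default (no 1.4826 normal-consistency factor); bins missing
    in either cell are ignored.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    d = d[np.isfinite(d)]
    scale = "normal" if scaled else 1.0
    return float(median_abs_deviation(d, scale=scale))


def _cn_difference(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.mean(a[ok] != b[ok]))


def mapd_metrics(ratio_matrix, groups, cn_matrix=None,
                 scaled: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell MAPD and per-group medians.

    The pairwise distance between two cells of the same group (protocol) is
    the MAD of their per-bin ratio difference; a cell's MAPD is the median
    of its within-group pairwise distances, and the group value is the
    median of its cells' MAPDs.  When ``cn_matrix`` is given the analogous
    metric on integer calls uses the fraction of bins with differing calls.
    Groups of size 1 get NaN with a warning.

    ``ratio_matrix``/``cn_matrix`` are cells x bins (DataFrame or ndarray);
    ``groups`` assigns each cell (row) a group label.
    """
    R = np.asarray(ratio_matrix, dtype=float)
    ids = (list(ratio_matrix.index) if isinstance(ratio_matrix, pd.DataFrame)
           else [f"cell{i}" for i in range(R.shape[0])])
    groups = np.asarray(groups)
    C = np.asarray(cn_matrix, dtype=float) if cn_matrix is not None else None
    cell_rows = []
    for g in dict.fromkeys(groups):
        members = np.flatnonzero(groups == g)
        if len(members) < 2:
            warnings.warn(f"group {g!r} has a single cell; MAPD undefined")
            cell_rows.append({"cell": ids[members[0]], "group": g,
                              "mapd_ratio": np.nan, "mapd_cn": np.nan})
            continue
        for i in members:
            dists = [pairwise_mad(R[i], R[j], scaled=scaled)
                     for j in members if j != i]
            row = {"cell": ids[i], "group": g,
                   "mapd_ratio": float(np.median(dists)), "mapd_cn": np.nan}
            if C is not None:
                cndists = [_cn_difference(C[i], C[j]) for j in members if j != i]
                row["mapd_cn"] = float(np.median(cndists))
            cell_rows.append(row)
    cells_df = pd.DataFrame(cell_rows)
    groups_df = (cells_df.groupby("group", sort=False)[["mapd_ratio", "mapd_cn"]]
                 .median().reset_index())
    return cells_df, groups_df
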