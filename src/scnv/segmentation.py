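"""Circular binary segmentation (CBS) of per-bin ratio profiles.

CBS partitions a noisy sequence into segments of constant mean by a
recursive changepoint search.  Each interval under consideration is treated
as a circle; among all arcs the algorithm finds the pair of changepoints
(i, j) maximizing the standardized two-sample statistic between the arc and
its complement,

    Z(i, j) = |sum(x[i:j]) - k * T / n| / sqrt(k * (n - k) / n),

with k = j - i the arc length, n the interval length and T the interval
sum.  (This is the mean-difference statistic under a fixed unit variance;
ranking of candidate splits is identical to the usual pooled two-sample
statistic, and the permutation test below makes the variance scale
irrelevant.)  The observed maximum is compared against the maxima obtained
by randomly permuting the interval values; if the permutation p-value is
below ``alpha`` the split is accepted and the resulting sub-intervals are
segmented recursively, otherwise the interval becomes a single segment.

Segmentation is performed independently per chromosome (breakpoints are
forced at chromosome boundaries) and runs on the compacted sequence of
unmasked bins; masked bins are re-expanded afterwards and inherit the
segment mean of the segment spanning them for display only.

Permutations are seeded per interval from (seed, chromosome, interval), so
decisions are reproducible and independent of the significance level used
to accept or reject other splits; lowering ``alpha`` can therefore only
remove breakpoints, never add them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
import pandas as pd

from .binning import VariableBinning
from .counting import RatioProfile

logger = logging.getLogger(__name__)

_PERM_BATCH = 256


@dataclass
class SegmentedProfile:
    """A per-bin piecewise-constant fit of a ratio profile.

    ``seg_mean`` carries the segment mean at each unmasked bin and NaN at
    masked bins; ``display_mean`` fills masked bins with the mean of the
    spanning segment.  ``segments`` has one row per segment with global bin
    coordinates (``start_bin`` inclusive, ``end_bin`` exclusive) and bp
    coordinates; ``breakpoints`` are global bin indices at which a new
    segment starts *within* a chromosome (chromosome starts excluded).
    """

    cell_id: str
    seg_mean: np.ndarray
    display_mean: np.ndarray
    segments: pd.DataFrame
    breakpoints: np.ndarray

    def __post_init__(self) -> None:
        self.seg_mean = np.asarray(self.seg_mean, dtype=float)
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.int64)


def cbs_statistic(x: np.ndarray, i: int, j: int) -> float:
    """Standardized circular two-sample statistic of arc ``x[i:j]``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = j - i
    if not 0 < k < n:
        raise ValueError("arc must be a proper subinterval")
    T = x.sum()
    return abs(x[i:j].sum() - k * T / n) / sqrt(k * (n - k) / n)


def _valid_starts(n: int, k: int, min_width: int) -> np.ndarray:
    """Validity mask over arc starts i = 0..n-k for arcs of length k.

    A split at (i, i+k) carves the interval into pieces [0, i), [i, i+k)
    and [i+k, n); every piece must be empty or at least ``min_width`` wide,
    so that no accepted split can create a segment narrower than
    ``min_width``.
    """
    i = np.arange(n - k + 1)
    j = i + k
    return ((i == 0) | (i >= min_width)) & ((j == n) | (j <= n - min_width))


def best_split(x: np.ndarray, min_width: int = 3):
    """Maximizing arc (i, j) of the circular two-sample statistic.

    Candidate arcs satisfy ``min_width <= j - i <= n - min_width`` and may
    not leave a non-empty edge piece narrower than ``min_width``.  Returns
    ``(i, j, stat)`` or ``None`` when no candidate exists or the maximal
    statistic is 0 (constant data).  Ties are broken by shorter arc, then by
    leftmost start.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return None
    S0 = np.concatenate([[0.0], np.cumsum(x)])
    T = S0[-1]
    best = (0.0, -1, -1)
    for k in range(min_width, n - min_width + 1):
        sums = S0[k:] - S0[: n - k + 1]
        z = np.abs(sums - k * T / n) / sqrt(k * (n - k) / n)
        z[~_valid_starts(n, k, min_width)] = -1.0
        i = int(np.argmax(z))
        if z[i] > best[0] * (1 + 1e-12):
            best = (float(z[i]), i, i + k)
    if best[1] < 0 or best[0] <= 0.0:
        return None
    return best[1], best[2], best[0]


def _max_stats_batch(X: np.ndarray, min_width: int) -> np.ndarray:
    """Row-wise maximum circular statistic for a batch of sequences.

    Uses the same candidate-arc constraints as :func:`best_split` so the
    permutation reference distribution matches the observed search.
    """
    B, n = X.shape
    S0 = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    T = S0[:, -1:]
    best = np.zeros(B)
    for k in range(min_width, n - min_width + 1):
        sums = S0[:, k:] - S0[:, : n - k + 1]
        z = np.abs(sums - k * T / n) / sqrt(k * (n - k) / n)
        z[:, ~_valid_starts(n, k, min_width)] = 0.0
        np.maximum(best, z.max(axis=1), out=best)
    return best


def _perm_pvalue(x: np.ndarray, observed: float, n_perm: int, min_width: int,
                 rng: np.random.Generator, alpha: float) -> float:
    """Permutation p-value of the observed maximal statistic.

    p = (1 + #{perm maxima >= observed}) / (1 + #permutations).  Permutation
    is processed in batches with early stopping: once enough exceedances
    have accumulated that the full-run p-value must exceed ``alpha``, the
    remaining permutations cannot change the accept/reject decision and are
    skipped (the returned conservative estimate is then only used as
    "not significant").
    """
    exceed = 0
    done = 0
    stop_at = ceil(alpha * (1 + n_perm))  # exceed >= stop_at => p >= alpha
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        X = rng.permuted(np.broadcast_to(x, (b, len(x))), axis=1)
        exceed += int((_max_stats_batch(X, min_width) >= observed - 1e-12).sum())
        done += b
        if exceed >= stop_at:
            return (1 + exceed) / (1 + done)
    return (1 + exceed) / (1 + n_perm)


def segment_series(x: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                   min_width: int = 3, seed: int = 0,
                   seed_entropy: tuple = ()) -> list[tuple[int, int]]:
    """Segment a single (chromosome's) sequence; returns (start, end) pairs.

    ``seed_entropy`` extends the per-interval seed derivation (used by the
    per-chromosome driver so each chromosome draws independent permutations).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    boundaries: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        cand = best_split(seg, min_width)
        if cand is None:
            continue
        i, j, stat = cand
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, *seed_entropy, lo, hi]))
        p = _perm_pvalue(seg, stat, n_perm, min_width, rng, alpha)
        if p >= alpha:
            continue
        cuts = [c for c in (lo + i, lo + j) if 0 < lo + (c - lo) < n and lo < c < hi]
        pieces = sorted({lo, hi, *cuts})
        boundaries.extend(c for c in cuts if 0 < c < n)
        for a, b in zip(pieces[:-1], pieces[1:]):
            stack.append((a, b))
    bounds = sorted({0, n, *boundaries})
    return list(zip(bounds[:-1], bounds[1:]))


def _undo_small_splits(x: np.ndarray, segs: list[tuple[int, int]],
                       undo_sd: float) -> list[tuple[int, int]]:
    """Merge adjacent segments whose standardized mean difference < undo_sd."""
    resid = np.concatenate([x[a:b] - x[a:b].mean() for a, b in segs])
    sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sd == 0:
        return segs
    segs = list(segs)
    while len(segs) > 1:
        stats = []
        for idx in range(len(segs) - 1):
            a0, b0 = segs[idx]
            a1, b1 = segs[idx + 1]
            t = abs(x[a0:b0].mean() - x[a1:b1].mean()) / (
                sd * sqrt(1 / (b0 - a0) + 1 / (b1 - a1)))
            stats.append(t)
        k = int(np.argmin(stats))
        if stats[k] >= undo_sd:
            break
        segs[k] = (segs[k][0], segs[k + 1][1])
        del segs[k + 1]
    return segs


def segment_cbs(profile: RatioProfile, bins: VariableBinning,
                alpha: float = 0.01, n_perm: int = 1000, min_width: int = 3,
                seed: int = 0, undo_splits: bool = False,
                undo_sd: float = 3.0) -> SegmentedProfile:
    """Segment a normalized ratio profile chromosome by chromosome.

    Masked bins are excluded from the series (each chromosome is segmented
    on its compacted unmasked bins and re-expanded afterwards).  Segment
    means are plain means of member bins, so the bin-weighted mean of the
    segment means equals the mean of the input ratios exactly.
    """
    ratio = profile.ratio
    good = ~bins.mask & np.isfinite(ratio)
    seg_mean = np.full(bins.n_bins, np.nan)
    display = np.full(bins.n_bins, np.nan)
    seg_rows = []
    breakpoints: list[int] = []
    starts_bp = bins.df["start"].to_numpy()
    ends_bp = bins.df["end"].to_numpy()
    for ci, (chrom, sl) in enumerate(bins.chrom_slices().items()):
        idx = np.nonzero(good[sl])[0] + sl.start  # global indices, unmasked
        if idx.size == 0:
            logger.info("%s: no unmasked bins, skipped", chrom)
            continue
        x = ratio[idx]
        segs = segment_series(x, alpha=alpha, n_perm=n_perm,
                              min_width=min_width, seed=seed,
                              seed_entropy=(ci,))
        if undo_splits and len(segs) > 1:
            segs = _undo_small_splits(x, segs, undo_sd)
        for si, (a, b) in enumerate(segs):
            members = idx[a:b]
            mean = float(x[a:b].mean())
            seg_mean[members] = mean
            # global span: from this segment's first unmasked bin up to the
            # next segment's first unmasked bin (or chromosome end)
            g_start = members[0] if si > 0 else sl.start
            g_end = idx[b] if b < len(idx) else sl.stop
            display[g_start:g_end] = mean
            seg_rows.append({
                "chrom": chrom, "start_bin": int(g_start), "end_bin": int(g_end),
                "n_bins": int(b - a), "mean": mean,
                "start_bp": int(starts_bp[g_start]), "end_bp": int(ends_bp[g_end - 1]),
            })
            if si > 0:
                breakpoints.append(int(members[0]))
    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start_bin", "end_bin", "n_bins", "mean",
                           "start_bp", "end_bp"])
    return SegmentedProfile(cell_id=profile.cell_id, seg_mean=seg_mean,
                            display_mean=display, segments=segments,
                            breakpoints=np.array(sorted(breakpoints), dtype=np.int64))
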