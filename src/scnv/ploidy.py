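"""Integer copy-number calling by quantal-error grid search.

In a single cell the copy number at any genomic position is an integer, so
a correctly scaled segmented profile must sit near integer values.  The
segmented ratios are centered around 1 (a diploid genome would be converted
to copy number by simply doubling), so for cells of unknown ploidy we scan
a grid of candidate multipliers — by default 1.5, 1.55, ..., 5.5, i.e. 81
values — and for each compute the *quantal error*: the sum over unmasked
bins of the squared difference between the multiplied segmented profile and
its nearest-integer rounding.  The multiplier minimizing the quantal error
is the best fit and defines the integer copy-number calls.

The quantal error doubles as a quality score: profiles that are not quantal
(doublets, fragments of cells, degraded or S-phase DNA) have a per-bin
error approaching 1/12, the variance of a fractional part uniform on
[-0.5, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _seg_values(seg) -> np.ndarray:
    """Per-bin segment means from a SegmentedProfile or a plain array."""
    values = getattr(seg, "seg_mean", seg)
    return np.asarray(values, dtype=float)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero.

    Fixed here (rather than numpy's round-half-to-even) so that errors at
    exact .5 boundaries are stable and documented.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class PloidyGrid:
    """Ordered grid of candidate ploidy multipliers (default 1.5-5.5/0.05)."""

    low: float = 1.5
    high: float = 5.5
    step: float = 0.05

    def __post_init__(self) -> None:
        if self.step <= 0 or self.high < self.low:
            raise ValueError("invalid grid bounds/step")

    @property
    def multipliers(self) -> np.ndarray:
        count = int(round((self.high - self.low) / self.step)) + 1
        return np.round(self.low + self.step * np.arange(count), 10)

    def __len__(self) -> int:
        return len(self.multipliers)


@dataclass
class CopyNumberProfile:
    """Integer copy-number calls for one cell.

    ``cn`` holds per-bin integer calls as floats with NaN at masked bins;
    ``nonrounded_cn`` is multiplier x segment mean.  ``error_curve`` records
    quantal error at every grid multiplier for QC plots.
    """

    cell_id: str
    multiplier: float
    quantal_error: float
    cn: np.ndarray
    nonrounded_cn: np.ndarray
    error_curve: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["multiplier", "quantal_error"]))

    @property
    def n_unmasked(self) -> int:
        return int(np.isfinite(self.cn).sum())


def quantal_error(seg, multiplier: float) -> float:
    """Sum over unmasked bins of (m*s_i - round(m*s_i))^2."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    s = _seg_values(seg)
    s = s[np.isfinite(s)]
    scaled = multiplier * s
    return float(np.sum((scaled - round_half_away(scaled)) ** 2))


def fit_ploidy(seg, grid: PloidyGrid | None = None,
               cell_id: str | None = None) -> CopyNumberProfile:
    """Select the grid multiplier with the smallest quantal error.

    Ties are broken toward the smallest multiplier (the most parsimonious
    ploidy; a perfectly flat profile fits exactly at every integer multiple).
    """
    grid = grid or PloidyGrid()
    s = _seg_values(seg)
    finite = np.isfinite(s)
    if not finite.any():
        raise ValueError("all-missing segmented profile")
    multipliers = grid.multipliers
    scaled = multipliers[:, None] * s[None, finite]
    errors = np.sum((scaled - round_half_away(scaled)) ** 2, axis=1)
    best = int(np.argmin(errors))  # first minimum -> smallest multiplier
    m = float(multipliers[best])
    nonrounded = np.where(finite, m * s, np.nan)
    cn = np.where(finite, round_half_away(nonrounded), np.nan)
    return CopyNumberProfile(
        cell_id=cell_id or getattr(seg, "cell_id", "cell"),
        multiplier=m,
        quantal_error=float(errors[best]),
        cn=cn,
        nonrounded_cn=nonrounded,
        error_curve=pd.DataFrame({"multiplier": multipliers,
                                  "quantal_error": errors}),
    )


def call_diploid(seg, cell_id: str | None = None) -> CopyNumberProfile:
    """Call a known-diploid cell by doubling the segmented profile."""
    s = _seg_values(seg)
    finite = np.isfinite(s)
    if not finite.any():
        raise ValueError("all-missing segmented profile")
    nonrounded = np.where(finite, 2.0 * s, np.nan)
    cn = np.where(finite, round_half_away(nonrounded), np.nan)
    err = float(np.nansum((nonrounded - cn) ** 2))
    return CopyNumberProfile(cell_id=cell_id or getattr(seg, "cell_id", "cell"),
                             multiplier=2.0, quantal_error=err,
                             cn=cn, nonrounded_cn=nonrounded)


def qc_quantal(profile: CopyNumberProfile, threshold: float = 0.05):
    """Quality-control check on the per-bin quantal error.

    Returns ``(passed, per_bin_error)``; a cell fails when its quantal error
    normalized per unmasked bin exceeds ``threshold``.  The uniform
    (non-quantal) limit of the per-bin error is 1/12 ~ 0.083.
    """
    n = profile.n_unmasked
    score = profile.quantal_error / n if n else np.inf
    return score <= threshold, float(score)
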