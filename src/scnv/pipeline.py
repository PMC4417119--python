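"""Convenience drivers chaining the per-cell analysis steps."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .binning import VariableBinning
from .counting import (BinCountProfile, RatioProfile, gc_correct_lowess,
                       normalize_counts)
from .ploidy import CopyNumberProfile, PloidyGrid, call_diploid, fit_ploidy, qc_quantal
from .segmentation import SegmentedProfile, segment_cbs

logger = logging.getLogger(__name__)


def call_cell(
    counts: BinCountProfile,
    bins: VariableBinning,
    *,
    span: float = 0.5,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
    grid: PloidyGrid | None = None,
    assume_diploid: bool = False,
    gc_correct: bool = True,
) -> tuple[RatioProfile, SegmentedProfile, CopyNumberProfile]:
    """normalize -> GC-correct -> segment -> quantal integer call."""
    ratio = normalize_counts(counts, bins)
    if gc_correct:
        ratio = gc_correct_lowess(ratio, bins, span=span)
    seg = segment_cbs(ratio, bins, alpha=alpha, n_perm=n_perm,
                      min_width=min_width, seed=seed)
    if assume_diploid:
        cnp = call_diploid(seg)
    else:
        cnp = fit_ploidy(seg, grid=grid)
    return ratio, seg, cnp


def call_population(count_matrix: pd.DataFrame, bins: VariableBinning,
                    qc_threshold: float = 0.05, seed: int = 0,
                    **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`call_cell` over a bins x cells count matrix.

    Returns (cells x bins integer CN DataFrame, per-cell stats DataFrame
    with multiplier, quantal error and QC flag).
    """
    cn_rows, stats = {}, []
    for k, cell in enumerate(count_matrix.columns):
        counts = BinCountProfile(cell_id=str(cell),
                                 counts=count_matrix[cell].to_numpy())
        _, _, cnp = call_cell(counts, bins, seed=seed + k, **kwargs)
        passed, score = qc_quantal(cnp, qc_threshold)
        cn_rows[str(cell)] = cnp.cn
        stats.append({"cell": str(cell), "multiplier": cnp.multiplier,
                      "quantal_error": cnp.quantal_error,
                      "per_bin_error": score, "qc_pass": passed})
    cn = pd.DataFrame.from_dict(cn_rows, orient="index")
    return cn, pd.DataFrame(stats).set_index("cell")
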