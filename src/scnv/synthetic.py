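"""Synthetic genomes, clonal copy-number profiles and sparse read sets.

The generator emulates the data structure of sparse single-cell whole-genome
amplification (WGA) sequencing:

* a small multi-chromosome genome with a mappability track (random
  unmappable gaps plus an unmappable centromere placeholder) and a smooth
  GC landscape in [0.3, 0.6];
* clonal populations of cells sharing integer copy-number profiles
  (baseline ploidy 2 with focal and arm-level events), optionally with
  per-cell private events;
* per-bin read counts whose expectation is proportional to
  copy number x mappable content x GC bias, drawn negative-binomially
  (gamma-Poisson) to model WGA overdispersion, with read positions uniform
  over each bin's mappable positions.

Every generator is deterministic under a fixed seed.  The default
overdispersion is tuned so that the per-bin ratio SD at ~40 reads/bin is
about 0.25, the noise scale of real sparse WGA data; the GC bias default is
a smooth unimodal multiplicative curve peaking at mid-GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .binning import MappabilityTrack, VariableBinning
from .counting import BinCountProfile

DEFAULT_OVERDISPERSION = 0.04  # ratio SD ~ sqrt(1/40 + 0.04) ~ 0.25 at 40 reads/bin


@dataclass(frozen=True)
class GCBias:
    """Smooth unimodal multiplicative amplification bias vs GC fraction."""

    peak: float = 0.45
    width: float = 0.08
    amplitude: float = 0.5  # 0 disables the bias

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return (1.0 - self.amplitude) + self.amplitude * np.exp(
            -0.5 * ((gc - self.peak) / self.width) ** 2)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a synthetic genome.

    ``mappable_fraction`` of each chromosome arm is uniquely mappable; the
    unmappable remainder is scattered as random gaps (mean length
    ``mean_gap_length``).  The middle ``centromere_fraction`` of each
    chromosome is an unmappable centromere placeholder.  The GC landscape is
    a smoothed random field mapped into ``gc_range``, piecewise constant on
    ``gc_window`` windows.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_000_000 for i in range(1, 5)})
    mappable_fraction: float = 0.9
    mean_gap_length: int = 500
    centromere_fraction: float = 0.04
    gc_range: tuple[float, float] = (0.3, 0.6)
    gc_window: int = 10_000

    def centromeres(self) -> dict[str, tuple[int, int]]:
        out = {}
        for chrom, length in self.chrom_lengths.items():
            half = int(length * self.centromere_fraction / 2)
            mid = length // 2
            out[chrom] = (mid - half, mid + half)
        return out


@dataclass(frozen=True)
class CNEvent:
    """A copy-number event over [start, end) bp of one chromosome."""

    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")
        if self.end <= self.start:
            raise ValueError("empty event span")


@dataclass(frozen=True)
class CloneSpec:
    name: str
    events: Sequence[CNEvent] = ()


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Sequencing parameters of one synthetic cell."""

    cell_id: str
    cn: np.ndarray  # per-bin integer copy number
    total_reads: int = 500_000
    gc_bias: GCBias = GCBias()
    overdispersion: float = DEFAULT_OVERDISPERSION
    duplicate_rate: float = 0.0


def generate_genome(spec: SyntheticGenomeSpec, seed: int = 0):
    """Generate (MappabilityTrack, genome sequences) for a genome spec."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 17]))
    intervals: dict[str, np.ndarray] = {}
    genome: dict[str, str] = {}
    centromeres = spec.centromeres()
    for chrom, length in spec.chrom_lengths.items():
        mappable = np.ones(length, dtype=bool)
        c_lo, c_hi = centromeres[chrom]
        mappable[c_lo:c_hi] = False
        # scatter random unmappable gaps over the arms
        arm_len = int(mappable.sum())
        target_gap = int(round(arm_len * (1.0 - spec.mappable_fraction)))
        placed = 0
        while placed < target_gap:
            glen = min(1 + rng.geometric(1.0 / spec.mean_gap_length),
                       target_gap - placed)
            pos = int(rng.integers(0, length - glen))
            seg = mappable[pos:pos + glen]
            placed += int(seg.sum())
            seg[:] = False
        # intervals of consecutive mappable positions
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mappable.view(np.int8), [0]])))
        intervals[chrom] = edges.reshape(-1, 2).astype(np.int64)
        # GC landscape: stationary AR(1) field mapped through its CDF into
        # gc_range.  Mean reversion matters: every GC stratum then recurs at
        # many loci across the genome (as in real genomes), which is what
        # keeps the downstream GC-bias fit identifiable — a random *walk*
        # can place an entire GC extreme in a single region, confounding GC
        # with any copy-number event that happens to sit there.
        n_win = length // spec.gc_window + 1
        # decorrelation ~5 windows (~50 kb): smooth at bin scale, yet any
        # megabase-scale CN event spans many GC strata, as in real genomes
        rho = 0.8
        noise = rng.normal(size=n_win)
        walk = np.empty(n_win)
        walk[0] = noise[0]
        for w in range(1, n_win):
            walk[w] = rho * walk[w - 1] + sqrt(1 - rho ** 2) * noise[w]
        lo, hi = spec.gc_range
        gc_win = lo + (hi - lo) * ndtr(walk)  # stationary N(0,1) -> U(0,1)
        gc = np.repeat(gc_win, spec.gc_window)[:length]
        # draw bases: G/C with probability gc, A/T otherwise
        u = rng.random(length)
        v = rng.random(length)
        bases = np.where(u < gc, np.where(v < 0.5, ord("G"), ord("C")),
                         np.where(v < 0.5, ord("A"), ord("T"))).astype(np.uint8)
        genome[chrom] = bases.tobytes().decode("ascii")
    track = MappabilityTrack(intervals=intervals,
                             chrom_lengths=dict(spec.chrom_lengths))
    return track, genome


def realize_cn_profile(bins: VariableBinning, events: Sequence[CNEvent],
                       baseline: int = 2) -> np.ndarray:
    """Per-bin integer CN from bp-coordinate events (bin midpoint rule).

    Overlapping events with contradictory copy numbers raise an error.
    """
    cn = np.full(bins.n_bins, baseline, dtype=np.int64)
    assigned = np.zeros(bins.n_bins, dtype=bool)
    mid = (bins.df["start"].to_numpy() + bins.df["end"].to_numpy()) // 2
    chrom = bins.df["chrom"].to_numpy()
    for ev in events:
        hit = (chrom == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
        clash = hit & assigned & (cn != ev.cn)
        if clash.any():
            raise ValueError(f"contradictory overlapping events at {ev}")
        cn[hit] = ev.cn
        assigned |= hit
    return cn


def generate_clones(clones: Sequence[CloneSpec], n_cells_per_clone: int,
                    bins: VariableBinning, seed: int = 0,
                    private_event_rate: float = 0.0,
                    private_event_bins: tuple[int, int] = (5, 20)):
    """Per-cell true CN profiles for a clonal population.

    Each cell inherits its clone's profile; private focal events (CN 1 or 3
    over a random run of bins) are added per cell at Poisson rate
    ``private_event_rate``.  Returns (cells x bins CN DataFrame, clone
    labels Series).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 29]))
    rows, labels, ids = [], [], []
    for clone in clones:
        base = realize_cn_profile(bins, clone.events)
        for i in range(n_cells_per_clone):
            cn = base.copy()
            for _ in range(rng.poisson(private_event_rate)):
                lo, hi = private_event_bins
                width = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, bins.n_bins - width))
                cn[start:start + width] = rng.choice([1, 3])
            cell = f"{clone.name}_{i:03d}"
            ids.append(cell)
            labels.append(clone.name)
            rows.append(cn)
    matrix = pd.DataFrame(np.array(rows), index=ids)
    return matrix, pd.Series(labels, index=ids, name="clone")


def _expected_bin_rates(cell: SyntheticCellSpec, bins: VariableBinning) -> np.ndarray:
    gc = bins.gc
    bias = cell.gc_bias(np.where(np.isfinite(gc), gc, 0.5))
    mapp = bins.df["mappable_count"].to_numpy(dtype=float)
    w = cell.cn * mapp * bias
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total expected counts")
    return cell.total_reads * w / total


def simulate_cell_counts(cell: SyntheticCellSpec, bins: VariableBinning,
                         seed: int = 0) -> BinCountProfile:
    """Draw per-bin counts directly (gamma-Poisson; Poisson when
    overdispersion is 0)."""
    if cell.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 41]))
    mu = _expected_bin_rates(cell, bins)
    if cell.overdispersion > 0:
        shape = 1.0 / cell.overdispersion
        lam = rng.gamma(shape, mu * cell.overdispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return BinCountProfile(cell_id=cell.cell_id, counts=counts)


def simulate_cell_reads(cell: SyntheticCellSpec, bins: VariableBinning,
                        track: MappabilityTrack, seed: int = 0) -> pd.DataFrame:
    """Emit single-end uniquely-mapping reads for one cell.

    Per-bin counts are drawn as in :func:`simulate_cell_counts`; read start
    positions are uniform over each bin's mappable positions, strands
    uniform.  PCR duplicates are injected at ``duplicate_rate`` (a fraction
    of extra reads re-sampled with replacement from the emitted ones).
    """
    counts = simulate_cell_counts(cell, bins, seed=seed).counts
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 43]))
    chrom_col, pos_col = [], []
    mapp = bins.df["mappable_count"].to_numpy()
    # per-chromosome mappable-ordinal offset of each bin
    ord_start = np.zeros(bins.n_bins, dtype=np.int64)
    for _, sl in bins.chrom_slices().items():
        ord_start[sl] = np.concatenate([[0], np.cumsum(mapp[sl])[:-1]])
    for chrom, sl in bins.chrom_slices().items():
        n_reads = counts[sl]
        total = int(n_reads.sum())
        if total == 0:
            continue
        bin_idx = np.repeat(np.arange(sl.start, sl.stop), n_reads)
        ordinals = ord_start[bin_idx] + (rng.random(total) * mapp[bin_idx]).astype(np.int64)
        positions = track.positions_of_ordinals(chrom, ordinals)
        chrom_col.append(np.full(total, chrom, dtype=object))
        pos_col.append(positions)
    if not chrom_col:
        raise ValueError("no reads emitted")
    chrom_arr = np.concatenate(chrom_col)
    pos_arr = np.concatenate(pos_col)
    strand = np.where(rng.random(len(pos_arr)) < 0.5, "+", "-")
    if cell.duplicate_rate > 0:
        n_dup = rng.poisson(cell.duplicate_rate * len(pos_arr))
        dup_idx = rng.integers(0, len(pos_arr), n_dup)
        chrom_arr = np.concatenate([chrom_arr, chrom_arr[dup_idx]])
        pos_arr = np.concatenate([pos_arr, pos_arr[dup_idx]])
        strand = np.concatenate([strand, strand[dup_idx]])
    order = rng.permutation(len(pos_arr))
    return pd.DataFrame({"chrom": pd.Categorical(chrom_arr[order]),
                         "pos": pos_arr[order], "strand": strand[order]})


def centromere_bin_mask(bins: VariableBinning,
                        spec: SyntheticGenomeSpec) -> np.ndarray:
    """Boolean mask of bins overlapping the centromere placeholders."""
    mask = np.zeros(bins.n_bins, dtype=bool)
    chrom = bins.df["chrom"].to_numpy()
    start = bins.df["start"].to_numpy()
    end = bins.df["end"].to_numpy()
    for c, (lo, hi) in spec.centromeres().items():
        mask |= (chrom == c) & (start < hi) & (end > lo)
    return mask
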