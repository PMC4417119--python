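"""Reproducible simulation studies exercising the whole pipeline.

These drivers build the synthetic inputs, run the analysis end to end and
measure recovery of the known truth.  They are shared by the test suite and
by ``scripts/acceptance.py``; every study is deterministic under its seed.

Problem sizes are deliberately desk-scale (a few-megabase genome, ~1000
bins, tens of cells); the quantities they measure — multiplier recovery,
breakpoint localization, bin-level copy-number accuracy, false-negative
rates — are properties of the method, not of the genome size.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .binning import MappabilityTrack, VariableBinning, compute_bin_gc, compute_variable_bins
from .counting import count_reads_in_bins, deduplicate_reads, gc_correct_lowess, normalize_counts
from .evaluation import (FNDesign, cn_concordance, downsample_reads,
                         match_bins, pairwise_mad, simulate_false_negatives,
                         false_positive_fraction)
from .pipeline import call_cell
from .ploidy import PloidyGrid, fit_ploidy
from .population import cluster_cells, cut_clusters
from .segmentation import best_split, cbs_statistic, segment_series
from .synthetic import (CloneSpec, CNEvent, GCBias, SyntheticCellSpec,
                        SyntheticGenomeSpec, centromere_bin_mask,
                        generate_clones, generate_genome, simulate_cell_counts,
                        simulate_cell_reads)


def _derive(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, salt]).generate_state(1)[0] & 0x7FFFFFFF)


def coverage_mean_reads_per_bin(total_reads: int, n_bins: int,
                                seed: int = 0) -> float:
    """Empirical mean reads/bin: uniform diploid reads counted in bins.

    Builds a synthetic genome partitioned into ``n_bins`` variable bins,
    emits ``total_reads`` uniquely mapping reads from a flat diploid genome
    (no GC bias, Poisson counting) and returns the mean per-bin count.
    """
    spec = SyntheticGenomeSpec(
        chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 5)},
        centromere_fraction=0.0)
    track, _ = generate_genome(spec, seed=_derive(seed, 1))
    bins = compute_variable_bins(track, n_bins)
    cell = SyntheticCellSpec(cell_id="flat", cn=np.full(bins.n_bins, 2),
                             total_reads=total_reads,
                             gc_bias=GCBias(amplitude=0.0), overdispersion=0.0)
    reads = simulate_cell_reads(cell, bins, track, seed=_derive(seed, 2))
    profile = count_reads_in_bins(reads, bins)
    return float(profile.counts.mean())


def multiplier_recovery(n_cells: int = 100, seed: int = 0,
                        noise_sd: float = 0.01) -> dict:
    """Recovery of random true ploidy multipliers by the quantal grid fit.

    Each synthetic cell has a true multiplier in [1.8, 4.5] and >= 5
    distinct integer CN states (guaranteed to include consecutive values so
    no smaller multiplier fits exactly); segment means are cn/multiplier
    plus Gaussian noise.  Success = fitted multiplier within one grid step
    of truth.
    """
    rng = np.random.default_rng(_derive(seed, 3))
    grid = PloidyGrid()
    hits = 0
    for _ in range(n_cells):
        true_m = float(rng.uniform(1.8, 4.5))
        base = int(round(true_m))
        states = np.arange(max(0, base - 2), base + 3)  # 5 consecutive states
        n_segs = 20
        cns = np.concatenate([states, rng.choice(states, n_segs - len(states))])
        rng.shuffle(cns)
        lengths = rng.integers(10, 100, n_segs)
        seg_mean = np.repeat(cns / true_m, lengths)
        seg_mean = seg_mean + rng.normal(0, noise_sd, len(seg_mean))
        fitted = fit_ploidy(seg_mean, grid).multiplier
        hits += abs(fitted - true_m) <= grid.step + 1e-9
    return {"recovered": hits, "n": n_cells, "rate": hits / n_cells}


def cbs_oracle_agreement(n_instances: int = 30, max_bins: int = 50,
                         seed: int = 0, min_width: int = 3) -> dict:
    """Agreement of the vectorized split search with brute-force enumeration.

    Random short sequences (some with a true step) are scanned exhaustively
    over all circular arc pairs (i, j) with the same width constraints; the
    implementation's chosen split must attain the enumerated maximum.
    """
    rng = np.random.default_rng(_derive(seed, 4))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2 * min_width, max_bins + 1))
        x = rng.normal(1.0, 0.2, n)
        if rng.random() < 0.5 and n >= 8:
            cut = int(rng.integers(2, n - 2))
            x[cut:] += rng.uniform(0.3, 1.0)
        res = best_split(x, min_width=min_width)
        brute = 0.0
        for i in range(n):
            for j in range(i + 1, n + 1):
                k = j - i
                if not (min_width <= k <= n - min_width):
                    continue
                if 0 < i < min_width or n - min_width < j < n:
                    continue  # edge piece narrower than min_width
                brute = max(brute, cbs_statistic(x, i, j))
        if res is None:
            agree += brute == 0.0
        else:
            agree += abs(res[2] - brute) <= 1e-9 * max(1.0, brute)
    return {"agree": agree, "n": n_instances, "rate": agree / n_instances}


def segmentation_null_rate(n_runs: int = 100, n_bins: int = 500,
                           sigma: float = 0.05, seed: int = 0, **seg_kwargs) -> dict:
    """Fraction of pure-noise chromosomes segmented as a single segment."""
    rng = np.random.default_rng(_derive(seed, 5))
    single = 0
    for r in range(n_runs):
        x = 1.0 + rng.normal(0, sigma, n_bins)
        segs = segment_series(x, seed=_derive(seed, 1000 + r), **seg_kwargs)
        single += len(segs) == 1
    return {"single": single, "n": n_runs, "rate": single / n_runs}


def segmentation_step_localization(n_runs: int = 100, half: int = 250,
                                   step: float = 0.5, sigma: float = 0.1,
                                   tol: int = 2, seed: int = 0,
                                   **seg_kwargs) -> dict:
    """Breakpoint localization on a step profile (two equal halves).

    Success = exactly two segments with the breakpoint within ``tol`` bins
    of the true changepoint.
    """
    rng = np.random.default_rng(_derive(seed, 6))
    hits = 0
    for r in range(n_runs):
        x = np.concatenate([np.full(half, 1.0), np.full(half, 1.0 + step)])
        x = x + rng.normal(0, sigma, 2 * half)
        segs = segment_series(x, seed=_derive(seed, 2000 + r), **seg_kwargs)
        if len(segs) == 2 and abs(segs[0][1] - half) <= tol:
            hits += 1
    return {"hits": hits, "n": n_runs, "rate": hits / n_runs}


def _two_clone_population(seed: int):
    """Shared layout of the two-clone benchmark population."""
    spec = SyntheticGenomeSpec()  # 4 x 2 Mb autosomes
    track, genome = generate_genome(spec, seed=_derive(seed, 7))
    bins = compute_variable_bins(track, 1000)
    bins = compute_bin_gc(bins, genome)
    L = spec.chrom_lengths["chr1"]
    shared = [CNEvent("chr1", int(0.10 * L), int(0.55 * L), 3),
              CNEvent("chr3", int(0.60 * L), int(0.80 * L), 1)]
    clone_a = CloneSpec("cloneA", shared + [
        CNEvent("chr2", int(0.20 * L), int(0.45 * L), 1),
        CNEvent("chr4", int(0.55 * L), int(0.70 * L), 4)])
    clone_b = CloneSpec("cloneB", shared + [
        CNEvent("chr2", int(0.55 * L), int(0.90 * L), 3),
        CNEvent("chr4", int(0.05 * L), int(0.30 * L), 1)])
    return spec, track, bins, [clone_a, clone_b]


def two_clone_benchmark(n_cells_per_clone: int = 25,
                        reads_per_cell: int = 500_000,
                        seed: int = 0) -> dict:
    """End-to-end recovery benchmark on a two-clone population.

    Generates reads for every cell, runs count -> dedup -> normalize ->
    GC-correct -> segment -> quantal call, scores per-cell bin-level CN
    accuracy against the generated truth, and checks that Ward/Manhattan
    clustering cut at k=2 recovers the clone labels (adjusted Rand index).
    """
    spec, track, bins, clones = _two_clone_population(seed)
    truth, labels = generate_clones(clones, n_cells_per_clone, bins,
                                    seed=_derive(seed, 8))
    accuracies = []
    cn_rows = {}
    for k, cell_id in enumerate(truth.index):
        cell = SyntheticCellSpec(cell_id=cell_id,
                                 cn=truth.loc[cell_id].to_numpy(),
                                 total_reads=reads_per_cell,
                                 duplicate_rate=0.02)
        reads = simulate_cell_reads(cell, bins, track, seed=_derive(seed, 100 + k))
        reads = deduplicate_reads(reads)
        counts = count_reads_in_bins(reads, bins, cell_id=cell_id)
        _, _, cnp = call_cell(counts, bins, seed=_derive(seed, 500 + k))
        ok = np.isfinite(cnp.cn)
        accuracies.append(float(np.mean(
            cnp.cn[ok] == truth.loc[cell_id].to_numpy()[ok])))
        cn_rows[cell_id] = cnp.cn
    cn = pd.DataFrame.from_dict(cn_rows, orient="index")
    clusters = cut_clusters(cluster_cells(cn), k=2)
    ari = float(adjusted_rand_score(labels.loc[clusters.index], clusters))
    return {
        "median_accuracy": float(np.median(accuracies)),
        "min_accuracy": float(np.min(accuracies)),
        "ari": ari,
        "n_cells": len(truth),
        "n_bins": bins.n_bins,
        "accuracies": accuracies,
    }


def downsample_concordance_study(reference_reads: int = 120_000,
                                 sizes: dict[int, int] | None = None,
                                 replicates: int = 3,
                                 seed: int = 0) -> pd.DataFrame:
    """Copy-number concordance of down-sampled calls vs a deep reference.

    A rearranged aneuploid cell is sequenced to ``reference_reads`` and
    called on a fine partition; subsamples of each size in ``sizes`` (a
    mapping size -> bin count, coarser partitions for smaller sizes, per
    the usual resolution/coverage trade-off) are re-called and compared
    bin-by-bin to the reference through a max-overlap bin match.  The
    default design is a scaled-down version of the standard 6M/2M/1M/250K
    ladder, keeping comparable reads-per-bin.
    """
    if sizes is None:
        sizes = {40_000: 1000, 20_000: 400, 10_000: 200}
    spec, track, bins_fine, clones = _two_clone_population(seed)
    from .synthetic import realize_cn_profile

    cn_true = realize_cn_profile(bins_fine, clones[0].events)
    cell = SyntheticCellSpec("deep", cn_true, total_reads=reference_reads)
    reads = deduplicate_reads(
        simulate_cell_reads(cell, bins_fine, track, seed=_derive(seed, 12)))

    _, genome = generate_genome(spec, seed=_derive(seed, 7))

    def call_on(reads_df, bins):
        counts = count_reads_in_bins(reads_df, bins, cell_id="cell")
        _, _, cnp = call_cell(counts, bins, seed=_derive(seed, 13))
        return cnp

    ref_cnp = call_on(reads, bins_fine)
    rows = []
    for m_requested, n_bins in sorted(sizes.items(), reverse=True):
        m = min(m_requested, len(reads))  # dedup shrinks the available pool
        bins_m = (bins_fine if n_bins == bins_fine.n_bins else
                  compute_bin_gc(compute_variable_bins(track, n_bins), genome))
        match = match_bins(bins_fine, bins_m)
        for rep in range(replicates):
            sub = downsample_reads(reads, m, seed=_derive(seed, 14) + rep)
            cnp = call_on(sub, bins_m)
            rows.append({"reads": m_requested, "n_bins": n_bins,
                         "reads_sampled": m, "replicate": rep,
                         "concordance": cn_concordance(ref_cnp, cnp, match)})
    return pd.DataFrame(rows)


def diploid_cohort(n_cells: int = 20, reads_per_cell: int = 60_000,
                   seed: int = 0):
    """GC-corrected ratio profiles of synthetic normal diploid cells.

    Reads-per-cell is chosen so bins average ~50-60 reads, giving a per-bin
    ratio SD ~ 0.25 — the noise scale of sparse WGA data.
    Returns (bins, genome spec, list of RatioProfile).
    """
    spec = SyntheticGenomeSpec()
    track, genome = generate_genome(spec, seed=_derive(seed, 9))
    bins = compute_variable_bins(track, 1000)
    bins = compute_bin_gc(bins, genome)
    cells = []
    for k in range(n_cells):
        cell = SyntheticCellSpec(cell_id=f"normal_{k:03d}",
                                 cn=np.full(bins.n_bins, 2),
                                 total_reads=reads_per_cell)
        counts = simulate_cell_counts(cell, bins, seed=_derive(seed, 300 + k))
        ratio = gc_correct_lowess(normalize_counts(counts, bins), bins)
        cells.append(ratio)
    return bins, spec, cells


def fn_rate_study(n_insertions: int = 170, n_cells: int = 20,
                  seed: int = 0, n_perm: int = 200) -> pd.DataFrame:
    """False-negative insertion simulation on a synthetic diploid cohort."""
    bins, spec, cells = diploid_cohort(n_cells=n_cells, seed=seed)
    design = FNDesign(n_insertions=n_insertions, seed=_derive(seed, 10))
    exclude = centromere_bin_mask(bins, spec)
    return simulate_false_negatives(cells, bins, design, n_perm=n_perm,
                                    exclude=exclude)


def diploid_false_positive_rate(n_cells: int = 20, seed: int = 0,
                                n_perm: int = 200) -> dict:
    """Fraction of bins called != 2 across a diploid cohort (upper bound on
    false-positive calls)."""
    from .ploidy import call_diploid
    from .segmentation import segment_cbs

    bins, _, cells = diploid_cohort(n_cells=n_cells, seed=seed)
    profiles = [call_diploid(segment_cbs(c, bins, n_perm=n_perm,
                                         seed=_derive(seed, 700 + i)))
                for i, c in enumerate(cells)]
    expected = np.full(bins.n_bins, 2.0)
    frac = false_positive_fraction(profiles, expected)
    return {"fraction": frac, "n_cells": n_cells, "n_bins": bins.n_bins}


def mapd_study(seed: int = 0, n_bins: int = 2000, n_cells: int = 6,
               sigma: float = 0.15) -> dict:
    """MAPD sanity study: oracle equivalence and the identical-cell limit.

    Checks the implementation's pairwise MAD against a direct numpy
    computation on random Gaussian profiles, reports the cohort MAPD, and
    the MAPD of a group of byte-identical cells (exactly 0).
    """
    from .evaluation import mapd_metrics

    rng = np.random.default_rng(_derive(seed, 11))
    R = 1.0 + rng.normal(0, sigma, size=(n_cells, n_bins))
    max_diff = 0.0
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            d = R[i] - R[j]
            oracle = float(np.median(np.abs(d - np.median(d))))
            max_diff = max(max_diff, abs(pairwise_mad(R[i], R[j]) - oracle))
    _, groups = mapd_metrics(R, ["g"] * n_cells)
    identical = np.tile(R[0], (3, 1))
    _, ident_groups = mapd_metrics(identical, ["g"] * 3)
    return {
        "oracle_max_abs_diff": max_diff,
        "cohort_mapd": float(groups["mapd_ratio"].iloc[0]),
        "identical_mapd": float(ident_groups["mapd_ratio"].iloc[0]),
        "n_pairs": n_cells * (n_cells - 1) // 2,
    }
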