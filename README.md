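# scnv — sparse single-cell copy-number profiling

`scnv` turns sparse single-cell sequencing data (a few hundred thousand to
a few million uniquely mapped reads per cell) into genome-wide **integer
copy-number profiles**, and provides the population analyses and
validation machinery that go with them. It is aimed at groups doing
highly multiplexed single-cell CNV work — tumor heterogeneity, clonal
structure, aneuploidy screening — where coverage per cell is deliberately
thin and the analysis must exploit the *quantal* (integer) nature of
single-cell copy number.

## The method

1. **Variable bins.** The genome is partitioned into N bins containing
   equal numbers of uniquely mappable positions (variable genomic span),
   so every bin has the same expected unique-read count at flat copy
   number. Recurrently over-covered "bad bins" are flagged from a panel
   of normal cells with a one-sided outlier threshold at tail probability
   1/N and masked.
2. **Ratios.** Deduplicated unique reads are counted per bin, divided by
   the cell's mean bin count, and corrected for GC amplification bias by
   lowess smoothing of ratio vs bin GC (multiplicative correction).
3. **Segmentation.** Circular binary segmentation (CBS) with permutation
   p-values partitions each chromosome into segments of constant mean
   (defaults α = 0.01, 1000 permutations, min width 3 bins; seeded and
   reproducible).
4. **Quantal calling.** The segmented profile s is scaled by each
   multiplier m on a grid (1.5, 1.55, …, 5.5 — 81 values) and the quantal
   error Σ_i (m·s_i − round(m·s_i))² is evaluated; the minimizing m yields
   integer calls cn_i = round(m·s_i). The per-bin quantal error doubles
   as a QC score (non-quantal profiles approach the uniform limit 1/12).
5. **Populations.** Cells cluster on integer CN profiles with Manhattan
   distance and Ward linkage (heatmaps, Newick dendrograms), embed with
   classical MDS, and a recurrence filter separates tumor cells from
   contaminating normals, giving a cellularity estimate.

The evaluation module implements read down-sampling with cross-resolution
concordance (max-overlap bin matching), false-negative estimation by
splicing simulated CN 1 and 3 segments into diploid profiles (deviations
scaled by √2 and 1/√1.5, central-bin call criterion), false-positive
accounting, and MAPD consistency metrics. A synthetic-data module
generates genomes, mappability tracks, clonal populations and
overdispersed sparse reads so every stage is testable without downloads.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from scnv import (SyntheticGenomeSpec, SyntheticCellSpec, generate_genome,
                  compute_variable_bins, compute_bin_gc, simulate_cell_reads,
                  deduplicate_reads, count_reads_in_bins, call_cell, qc_quantal)

spec = SyntheticGenomeSpec()                       # 4 chromosomes x 2 Mb
track, genome = generate_genome(spec, seed=7)
bins = compute_bin_gc(compute_variable_bins(track, 1000), genome)

cn_true = np.full(bins.n_bins, 2)                  # diploid baseline ...
cn_true[100:220] = 3                               # ... with a gain on chr1
cn_true[600:680] = 1                               # ... and a loss on chr3
cell = SyntheticCellSpec("demo", cn_true, total_reads=500_000)
reads = deduplicate_reads(simulate_cell_reads(cell, bins, track, seed=7))
counts = count_reads_in_bins(reads, bins, cell_id="demo")

ratio, seg, cnp = call_cell(counts, bins, seed=7)
passed, per_bin = qc_quantal(cnp)
print(f"reads counted : {counts.total_reads}")
print(f"segments      : {len(seg.segments)}  breakpoints at bins {[int(b) for b in seg.breakpoints]}")
print(f"multiplier    : {cnp.multiplier:.2f}   quantal error/bin: {per_bin:.4f}   QC pass: {passed}")
ok = np.isfinite(cnp.cn)
print(f"CN accuracy   : {100*np.mean(cnp.cn[ok] == cn_true[ok]):.1f}% of bins match the simulated truth")
```

prints

```
reads counted : 490720
segments      : 8  breakpoints at bins [101, 220, 599, 680]
multiplier    : 2.05   quantal error/bin: 0.0006   QC pass: True
CN accuracy   : 99.8% of bins match the simulated truth
```

The ~490K counted reads are the 500K simulated reads minus coincidental
(chromosome, position, strand) collisions removed by deduplication —
sparse data are dense enough for birthday collisions; 8 segments over 4 chromosomes means both
event boundaries were found (within a bin) and nothing else; the fitted
multiplier 2.05 sits one grid step from the cell's true mean copy number
2.07, and the per-bin quantal error 0.0006 is far below the 0.05 QC
threshold — a cleanly quantal profile.

A shell workflow over files (`scnv bins`, `scnv count`, `scnv normalize`,
`scnv segment`, `scnv call`, `scnv cluster`, `scnv mds`, …) wraps the same
functions; run `scnv --help`.

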