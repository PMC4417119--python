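# Methods

`scnv` estimates genome-wide integer copy-number profiles of single cells
from sparse sequencing (hundreds of thousands to a few million reads per
cell), and ships the simulation machinery used to validate the estimates.
This note documents the model, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Model and procedure

**Variable bins.** Read-depth copy-number estimation counts uniquely
mapping reads in genomic windows. `scnv` uses windows of *equal uniquely
mappable content* rather than equal genomic span: given a mappability
track, the genome is partitioned into N bins each containing the same
number of uniquely mappable positions, so that under a flat copy-number
landscape every bin has the same expected read count regardless of local
repeat content. Bin spans therefore vary, stretching across poorly
mappable regions. The bin total is apportioned across chromosomes
proportionally to mappable content (largest-remainder rounding, at least
one bin per chromosome with content); within a chromosome each bin gets
floor(m/n) positions and the division remainder goes to the chromosome's
last bin. Boundaries sit on each bin's first mappable position; the first
bin of a chromosome starts at 0 and the last ends at the chromosome
length, so bins tile chromosomes exactly and never span two chromosomes.
All coordinates are 0-based, half-open.

**Bad bins.** Some regions (mostly pericentromeric) accumulate anomalously
high depth in every library. From a panel of ≥2 normal cells: counts are
divided by each cell's mean, the per-chromosome mean over all cells is
subtracted, and mean/SD are estimated over autosomal adjusted values. A
bin is flagged when its cross-cell mean adjusted value exceeds the
one-sided upper threshold mean + z·SD, with z the standard-normal quantile
at tail probability 1/N — i.e. about one false flag expected genome-wide
under the null. The test is one-sided because the artifact is excess
depth; sex chromosomes are excluded from the mean/SD estimate (male cells
sit near ratio 0.5 there) but remain flaggable. Flagged bins are masked
from all downstream analysis.

**Ratios and GC correction.** Deduplicated unique-read counts per bin
(dedup key: chromosome, 5′ start, strand; reads assigned to bins by their
5′ start under the half-open convention) are divided by the cell's mean
count over unmasked bins, giving ratios with mean exactly 1. Whole-genome
amplification introduces a smooth multiplicative GC bias; a lowess fit of
ratio on bin GC fraction (span 0.5) is divided out and the profile
re-normalized. The correction is multiplicative and on the natural (not
log) scale because amplification efficiency scales counts
multiplicatively; the span is a default, not a claim — the fit is
insensitive to it in the 0.3–0.7 range on our synthetic bias shapes.
Degenerate GC ranges return the input unchanged with a warning.

**Segmentation (CBS).** Each chromosome's compacted unmasked ratio series
is segmented by circular binary segmentation: treat the interval as a
circle, find the arc (i, j) maximizing the standardized two-sample
statistic between arc and complement,

    Z(i,j) = |S(i,j) − k·T/n| / √(k(n−k)/n),

accept the split when its permutation p-value (p = (1+exceed)/(1+n_perm))
is below α, and recurse on the pieces. Defaults α = 0.01, n_perm = 1000,
min_width = 3, matching common practice for sparse single-cell data.
Candidate arcs may not create any non-empty piece narrower than
min_width — this includes the edge pieces [0, i) and [j, n), which
suppresses spurious 1–2-bin edge segments. The same candidate set is used
for the permutation maxima, so the reference distribution matches the
observed search. Permutations are seeded per (seed, chromosome, interval),
which makes decisions reproducible and α-monotone: lowering α can only
remove breakpoints. Early stopping skips remaining permutations once the
accept/reject decision is mathematically settled; it never changes a
decision. Segment means are plain means of member bins, so the
bin-weighted mean of segment means equals the profile mean exactly.
Masked bins inherit the spanning segment's mean for display only. An
optional undo-splits pass merges adjacent segments whose standardized mean
difference falls below a threshold (off by default; quantal rounding
downstream absorbs small spurious splits).

**Quantal integer calling.** Copy number in a single cell is integral, so
a correctly scaled segmented profile must sit near integers. For each
candidate multiplier m on a grid (default 1.5 to 5.5 in steps of 0.05 — 81
values) the *quantal error* Σ_bins (m·s_i − round(m·s_i))² is evaluated on
the per-bin segmented profile (segments thereby weighted by length); the
minimizing m defines the calls cn_i = round(m·s_i). Ties break to the
smallest multiplier — a perfectly flat profile fits exactly at every
integer multiple, and the smallest is the most parsimonious ploidy.
Rounding is half-away-from-zero, fixed so errors at exact .5 boundaries
are stable. Known-diploid cells can skip the grid (`assume_diploid`,
multiplier 2). The per-bin quantal error is also a QC score: non-quantal
profiles (doublets, degraded DNA, S-phase cells) approach the
uniform-fractional-part limit 1/12 ≈ 0.083; the default failure threshold
is 0.05 per bin.

**Population analysis.** Cells are clustered on their integer CN vectors
(not ratios) with Manhattan distance and Ward linkage; cells are sorted by
id before linkage so leaf order is deterministic and input-order
independent. Embeddings use classical (Torgerson) MDS of the Manhattan
distance matrix — deterministic, with component signs fixed — or
optionally seeded metric-stress MDS. Tumor-cell selection is a simple
recurrence filter (cell altered over > f of autosomal bins, altered bins
overlapping regions altered in ≥ r of aberrant cells; defaults f = 0.05,
r = 0.25); it stands in for a full recurrent-event significance analysis
and is disclosed as such.

## Evaluation machinery

* **Down-sampling:** seeded uniform subsampling of reads without
  replacement; profiles called at coarser resolutions are compared to a
  deep reference through a max-overlap bin match (each fine bin mapped to
  the coarse bin of maximal genomic overlap, ties to the earlier bin).
  Copy-number concordance is the fraction of jointly unmasked reference
  bins whose call matches the matched test bin. Breakpoint concordance
  maps reference breakpoints through the match and counts those with a
  test breakpoint within tol coarse bins (default 1; exact-bin matching
  across partitions of different size is ill-posed).
* **False negatives:** segments of copy number 1 or 3 and odd length L are
  spliced into GC-corrected diploid ratio profiles at random runs of
  contiguous autosomal bins avoiding masked bins, a centromere exclusion
  mask, and chromosome-terminal bins. The splice is an affine transform
  consistent with Poisson count scaling: CN1 v′ = 0.5 + √2(0.5r − 0.5)
  (deviations up by √2), CN3 v′ = 1.5 + (1.5r − 1.5)/√1.5 (deviations of
  the 1.5-scaled values down by √1.5 — net deviations √1.5 larger than
  the diploid baseline, which is why CN3 segments are harder to detect).
  The affected chromosome is re-segmented (exact, since segmentation is
  per-chromosome) and a false negative is scored when the doubled, rounded
  segment mean at the *central bin* differs from the inserted CN.
* **MAPD:** the pairwise distance between two same-protocol cells is the
  (unscaled) median absolute deviation of their per-bin ratio difference;
  a cell's MAPD is the median of its within-group pairwise distances, and
  the group value the median over cells. A flag enables the 1.4826
  normal-consistency scaling. The integer-call analogue uses the fraction
  of bins with differing calls.

## Synthetic data: what it emulates, what it does not

The generator produces multi-chromosome genomes (default 4 × 2 Mb) with an
unmappable centromere placeholder, random unmappable gaps (default 90%
mappable), and a smooth GC landscape in [0.3, 0.6]. The GC field is a
*stationary* (mean-reverting) AR(1) process with ~50 kb correlation
length mapped through its CDF into the target range — stationarity is
deliberate: it guarantees every GC stratum recurs at many loci, so a
large copy-number event always spans many strata, as in real genomes. (A
non-stationary field, e.g. a random walk, can place an entire GC extreme
inside one region; the lowess GC fit then absorbs the copy-number signal
of any event sitting there, a confound real genomes do not exhibit at
that strength.) Clonal populations are generated as
baseline-2 integer profiles with arm-level and focal events plus optional
Poisson private events; and reads/counts with expectation ∝ copy number ×
mappable content × GC bias, drawn gamma-Poisson. The overdispersion
default 0.04 makes the per-bin ratio SD ≈ √(1/μ + 0.04) ≈ 0.25 at ~40
reads/bin, the noise scale of real sparse WGA data (a tuning choice, not a
measured constant); the GC bias default is a smooth unimodal curve peaking
at GC 0.45. Everything is byte-deterministic under its seed.

Passing the synthetic studies demonstrates correctness of the machinery —
binning conservation, count bookkeeping, segmentation localization, grid
recovery, clustering — under a model with independent bins, stationary
noise, and a smooth single-peaked GC bias. Real WGA data additionally
show locus-specific amplification artifacts, correlated noise along the
genome, mappability errors, and cell-cycle effects; the synthetic results
therefore bound the method's behavior from the favorable side, and the
false-negative percentages measured here are properties of the chosen
noise level, not predictions for any particular dataset.

## Problem sizes and numerics

Simulation studies run on a 1000-bin genome with 50 cells end-to-end at
500K reads/cell, 100 seeded runs for the segmentation null/step studies,
170 insertions per (CN, length) combination for the false-negative
study, and a down-sampling ladder of 40K/20K/10K reads at 1000/400/200
bins against a 120K-read reference (the classic coverage/resolution
trade-off at comparable reads-per-bin) — sizes chosen so the whole
validation battery completes in minutes
on one CPU while keeping binomial error on the measured rates a few
percent. Numerical conventions worth knowing: grid multipliers are
rounded to 10 decimals so nominal values like 2.0 are exact; quantal-error
ties take the first (smallest) grid minimum; the CBS statistic tie-breaks
by shorter arc then leftmost start; empty chromosomes segment to nothing;
`n_perm` below 100 warns; all fractions are reported in [0, 1] internally
and converted to percentages only at the reporting layer.

## Known limitations

Single-end reads only; no allele-specific copy number or SNVs; no joint
multi-sample segmentation; the recurrence filter is not a significance
test; mappability tracks are consumed, never computed; breakpoint
concordance depends on the chosen tolerance; CBS parameters interact with
downstream concordance measures on real data, so cross-dataset comparisons
should fix α, n_perm and min_width.
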