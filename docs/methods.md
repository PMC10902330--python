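# Methods

## Rhythm model and test

Each gene's log2 expression series is modeled as a single cosine
(cosinor): `y(t) = M + a·cos(2πt/T) + b·sin(2πt/T) + ε`, solved exactly by
least squares (no iterative optimizer). Derived parameters: mesor `M`
(rhythm-adjusted mean), amplitude `2·√(a²+b²)` — **peak-to-trough on the
log2 scale**, so amplitude 1 corresponds to roughly a 2-fold oscillation —
and phase `atan2(b, a) mod 2π`, the peak position in radians relative to
t = 0 of the analyzed segment (the default designs start at 0 h, so the
origin is the first sample). A `half_range` amplitude convention
(`√(a²+b²)`) is selectable; no variance-ratio amplitude is offered because
its exact definition in upstream tooling is ambiguous.

The period is chosen on a grid (default step 0.5 h; only the window
endpoints are scientifically fixed) by minimal residual sum of squares,
ties broken toward the shortest period with a small relative tolerance so
floating-point noise on flat series cannot flip the choice. The
periodicity statistic is the variance explained at the best grid period,
`1 − RSS_best/RSS_0` with `RSS_0` the intercept-only residual. Its null is
a permutation distribution: timepoint labels are shuffled with replicate
blocks kept intact, the identical permutation sequence applied to every
gene, and `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`. Observed and permuted
residuals are both computed by QR projection so any rank-deficient period
inside a user-chosen window is treated identically on both sides.
Benjamini–Hochberg correction runs per analysis run (per condition), never
pooled across conditions. Genes are called rhythmic by strict
`q < q_thr` **and** `amplitude > amp_thr`; the standard threshold sets are
(0.05, –) for the strict clustering set, (0.10, 1) for phase-distribution
analyses and (0.30, 0) for low-power knockdown comparisons. A neural-net
periodicity classifier used in some published analyses is intentionally
not reimplemented: the parameter estimates there are cosine-fit based
anyway, and a permutation-calibrated cosinor statistic has a transparent
null.

The test refuses matrices with fewer than 8 distinct timepoints or with
mixed conditions (subset first), and requires ≥ 99 permutations. When a
design mixes an entrained and a free-running segment the default is to fit
all timepoints jointly; restriction to a segment is the caller's subset.

## Clustering and phase bins

Waveform clustering uses replicate-averaged profiles, mean-centered and
scaled to unit norm ("amplitude normalization"), agglomerative linkage
(average by default; complete/single selectable) on cosine distance
`1 − x·y/(‖x‖‖y‖)`, cut to a requested cluster count. Replicate-averaged
input was chosen because the published heatmaps show one row per gene; the
alternative (per-replicate rows) is not offered. A min–max mode
(max = 1, min = 0; constant series map to zeros) supports knockdown
heatmap comparisons. Phase bins are half-open `[lower, upper)` intervals;
defaults are the three observed adult phase peaks `[π/6, π/2)` (magenta),
`[π/2, 5π/6)` (navy), `[4π/3, 5π/3)` (gray). Phases outside every bin get
the label `other`, making assignment total; bins are configuration, not
detected — peak finding in the phase histogram is out of scope.

## Regulatory regions and motif scanning

A gene's regulatory region is the 4 kb upstream of its first exon
(strand-aware; for multi-transcript genes the exons are merged and the
5′-most first exon is used) plus all introns. Upstream windows truncate at
contig boundaries only; overlap with neighboring genes is not trimmed, as
no such rule is defined for this analysis. Internal coordinates are
0-based half-open; GFF3 I/O converts from 1-based inclusive.

IUPAC motifs are scanned with a position-by-position allowed-base table
over the byte-encoded sequence; all overlapping starts count, and by
default both strands are scanned (RORE is non-palindromic and strand usage
is not documented upstream; single-strand scanning is a switch). An `N` in
the genome satisfies only the motif code `N`. Since enrichment uses only
per-gene presence/absence, the overlap and strand conventions cannot
change enrichment conclusions. D-box (`TTATGYAA`), E-box (`CACGTG`) and
E′-box (`CACGTT`) consensus strings are package defaults and fully
configurable, because no authoritative strings are printed for this
organism's analysis.

## Enrichment, overlap and condition comparison

For each tested phase bin × motif, the 2×2 table is presence vs bin
membership with background = all other analysis-universe genes (other
peaks + arrhythmic; an arrhythmic-only background is selectable). The
two-sided Fisher exact p uses the probability-mass criterion for
extremeness, with ties included up to a 1e-7 relative tolerance (the
convention of the underlying SciPy routine; other two-sided definitions
differ only in such edge cases). The reported odds ratio is the sample
`ad/bc` (∞ when `bc = 0` with `ad > 0`, NaN on a zero margin, where p = 1).
Holm's step-down correction runs across all bin × motif pairs of one run
by default; per-motif families are selectable since the published family
is ambiguous. The analysis universe is always an explicit argument.

Dual-period overlap reports the fraction of circadian-rhythmic genes that
are also developmentally rhythmic, overall and per phase bin, with a
hypergeometric upper-tail p for over-representation. The condition
comparison fits independent rhythm tables per condition, flags genes
rhythmic in the reference but not the treatment as "lost", and situates
counts against a time-shuffled null (timepoint labels permuted with
replicate blocks intact, full test re-run per shuffle with derived seeds).

## Synthetic data: what it emulates and what it does not

The generator renders `M + (A/2)·cos(2πt/T − φ)` plus i.i.d. Gaussian
noise on the log2 scale, under three sampling designs: circadian
(12 × 4 h × 3 replicates), developmental (16 × 1 h × 1 replicate) and
knockdown (12 × 2 h × 2 replicates × 2 conditions). Defaults, chosen once
as field-realistic study conditions:

- `noise_sd = 0.25` log2 units. The real datasets' noise magnitude is not
  documented, so this is a configuration value, not a claim about the
  data.
- baseline (mesor) ~ Normal(6, 1.5) log2 units, typical of log TPM/array
  intensities.
- amplitude ~ Normal(1.5, 0.5) truncated at 0. Truncation (not
  re-drawing) keeps the consumed random stream fixed-length, so runs are
  reproducible regardless of how many draws would have been negative.
- phase ~ 3-component wrapped-normal mixture centered at π/3, 2π/3, 3π/2
  (sd 0.15, equal weights), mimicking the three observed adult phase
  peaks; weights and components are configurable.
- period: fixed 24 h in the circadian design (entrained conditions),
  Uniform(8, 10) h in the developmental design, 8.5 h for planted
  dual-clock oscillators.
- knockdown: the target condition's oscillatory component is multiplied
  by `amplitude_scale`; noise for the regenerated block is re-drawn from
  a stream derived from the stored design seed, so the operation is
  deterministic from the truth object.

The toy genome draws i.i.d. background bases, lays out non-overlapping
multi-exon genes (alternating strands, ≥ 4 kb + spacing apart so
regulatory regions never collide), and per gene × motif plants — with a
cluster-dependent probability — one concrete expansion of the IUPAC string
(uniform over allowed bases, uniform strand) at a position uniform over
all valid starts of the regulatory parts; planted instances never
overwrite each other (resampled on collision). Planted counts and
positions are recorded as truth.

Not emulated: replicate batch effects (an i.i.d.-noise flag away from
reality), heteroskedastic count noise, non-sinusoidal waveforms
(sawtooth-like molting expression), probe/read-level artifacts,
transcript isoforms, chromatin context, and real intergenic structure.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under the stated generative model — not
performance on any real GEO dataset.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to give tight binomial/Poisson
bounds while keeping the default suite quick: 500 genes × 999 permutations
for null calibration; 1000 (circadian) and 600 (developmental) genes for
parameter recovery; a 5000-gene universe with 300 rhythmic (~100 per phase
bin, the arrhythmic pool scaling down a ~20k-transcript array universe)
for the end-to-end enrichment analogue, 10 seeds; 1000 genes with 200
rhythmic, 199 permutations and 20 shuffles for the knockdown analogue.
The amplitude-zero convention reports phase 0 whenever the fitted
amplitude is below 1e-9; fcluster/linkage tie-breaking follows SciPy's
lowest-index merge; TSV floats are written at 6 significant digits for
reproducible diffs; every output table can carry the config hash and seed
in a header comment.

## Known limitations

- Permutation p-values have resolution `1/(n_perm+1)`; with 199
  permutations the smallest attainable q values are limited accordingly.
- With 12 × 2 h sampling the window covers less than one full circadian
  cycle; period estimates at the window edges are weakly identified
  (phase/amplitude remain well-estimated).
- The Fisher universe choice materially affects enrichment; it is an
  explicit input precisely because the right universe (all probes vs
  expressed genes) is analysis-dependent.
- Upstream regions may overlap neighboring genes' exons by design; BED
  audit output lets users inspect and filter if they prefer trimming.
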