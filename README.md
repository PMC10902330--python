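# wormclock

Rhythm detection and cis-element enrichment for *C. elegans* time-course
transcriptomics.

Adult *C. elegans* show weak but real circadian (~24 h) transcriptional
rhythms after temperature entrainment, while larvae run an ~8-h
developmental (molting) clock. Genes carrying the ROR response element
(RORE, IUPAC consensus `WAWNTRGGTCA`) — the element bound by the
*Ror* homolog *nhr-23* — oscillate in a specific circadian phase in
adults and on the 8-h timescale in larvae. `wormclock` packages the
computational chain needed to make and check such claims:

1. **Rhythm detection** — per gene, the cosinor model
   `y(t) = M + (A/2)·cos(2πt/T − φ)` is fitted by exact least squares at
   every period `T` on a grid inside a window (20–28 h circadian,
   8–10 h developmental). The periodicity statistic is the variance
   explained at the best period, `1 − RSS_best/RSS_0`; its null comes from
   permuting timepoint labels (replicate blocks intact, identical
   permutations for all genes), and p-values are Benjamini–Hochberg
   adjusted. Amplitude `A` is peak-to-trough in log2 units (A = 1 ≈
   2-fold); phase `φ ∈ [0, 2π)` is the peak position relative to t = 0.
2. **Clustering & phase bins** — amplitude-normalized profiles are
   clustered agglomeratively under cosine distance; rhythmic genes are
   assigned to half-open phase bins (defaults `[π/6, π/2)`, `[π/2, 5π/6)`,
   `[4π/3, 5π/3)`).
3. **Regulatory regions & motifs** — each gene's 4 kb upstream of the
   first exon plus all introns is extracted from FASTA+GFF3 and scanned
   for degenerate IUPAC motifs on both strands.
4. **Enrichment, overlap, knockdown** — per phase bin × motif, a
   two-sided Fisher exact test on motif presence vs the rest of the
   universe, Holm-corrected; hypergeometric overlap between circadian and
   developmental gene sets; mock-vs-knockdown comparison against a
   time-shuffled null.
5. **Synthetic data** — generators for the three sampling designs
   (12 × 4 h × 3 reps; 16 × 1 h × 1 rep; 12 × 2 h × 2 reps × 2 conditions)
   and toy genomes with motifs planted at known positions, so the whole
   chain is testable offline against planted ground truth.

## Worked example

```python
import numpy as np
from wormclock import (circadian_design, simulate_expression,
                       rhythm_test, classify_rhythmic)

design = circadian_design(seed=1, noise_sd=0.25)   # 12 x 4 h x 3 replicates
matrix, truth = simulate_expression(design, n_genes=500, frac_rhythmic=0.2)
table = rhythm_test(matrix, period_min=20, period_max=28,
                    n_permutations=499, seed=1)
detected = classify_rhythmic(table, q_threshold=0.10, amplitude_threshold=1.0)
planted = truth.genes.query("is_rhythmic and amplitude_log2 >= 1").index
print(len(detected), np.mean([g in detected for g in planted]))
```

prints `85 0.989...`: 85 genes pass the selection `q < 0.10` with
amplitude > 1 (≈ 2-fold peak-to-trough), and 99% of the planted genes
oscillating at least 2-fold are among them. The same chain continued into
motif enrichment (see `examples/03_motif_enrichment.py`, RORE planted in
80% of early-phase genes vs 20% background) prints

```
    bin   a   b    c    d  odds_ratio        p_holm
magenta  65  15  145  415   12.402299  1.566708e-20
   navy  22  58  188  372    0.750550  1.000000e+00
   gray  17  63  193  367    0.513118  2.362146e-01
```

— RORE presence is enriched only in the bin where it was planted.
Each script under `examples/` demonstrates one capability end to end:
simulation + detection, phase clustering, motif enrichment, dual-clock
overlap, and knockdown comparison. A thin CLI (`wormclock simulate`,
`rhythm`, `cluster`, `phasebin`, `regions`, `scan`, `enrich`, `overlap`,
`shufflenull`, `compare`, `pipeline`) wraps the same functions for shell
use.

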