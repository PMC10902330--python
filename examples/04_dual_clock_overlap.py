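"""Overlap between circadian (24 h, adult) and developmental (8.5 h,
larval molting) rhythmic gene sets.

Plants a subset of circadian genes as ultradian oscillators in an
independent 16 x 1 h larval design and measures, per phase bin, what
fraction of circadian genes is also developmentally rhythmic.
"""

import numpy as np
import pandas as pd

from wormclock import (
    DEFAULT_AMPLITUDE_DIST,
    SyntheticTruth,
    assign_phase_bins,
    circadian_design,
    classify_rhythmic,
    developmental_design,
    dual_period_overlap,
    rhythm_test,
    simulate_expression,
    simulate_from_truth,
)

seed = 4
matrix, truth = simulate_expression(
    circadian_design(seed=seed, noise_sd=0.25), 800, 0.3,
    cluster_labels=["magenta", "navy", "gray"],
)
table = rhythm_test(matrix, 20, 28, n_permutations=499, seed=seed)
circ = sorted(classify_rhythmic(table, 0.10, 1.0))
bins = assign_phase_bins(table.loc[circ, "phase_rad"])

rng = np.random.default_rng(seed)
g = truth.genes
dev_flag = rng.random(len(g)) < np.where(g["cluster"] == "magenta", 0.25, 0.10)
dd = developmental_design(seed=seed + 1, noise_sd=0.25)
dev_truth = SyntheticTruth(genes=pd.DataFrame({
    "is_rhythmic": dev_flag,
    "period_h": np.where(dev_flag, 8.5, 0.0),
    "phase_rad": np.where(dev_flag, rng.uniform(0, 2 * np.pi, len(g)), 0.0),
    "amplitude_log2": np.where(dev_flag, DEFAULT_AMPLITUDE_DIST.draw(rng, len(g)), 0.0),
    "mesor": g["mesor"], "cluster": "none"}, index=g.index), design=dd)
dev_matrix = simulate_from_truth(dd, dev_truth)
dev_table = rhythm_test(dev_matrix, 8, 10, n_permutations=499, seed=seed + 2)
dev = sorted(classify_rhythmic(dev_table, 0.10, 1.0))

result = dual_period_overlap(circ, dev, list(g.index), bins)
print(f"overall overlap: {100 * result.proportion:.1f}% "
      f"(hypergeometric p = {result.p_hypergeom:.3g})")
for label, info in sorted(result.per_bin.items()):
    print(f"  {label:8s} {info['overlap']:3d}/{info['size']:3d} = {100 * info['proportion']:.1f}%")
# The magenta (early-phase) bin was planted with a 25% dual-clock rate vs
# 10% elsewhere, so its overlap percentage should clearly exceed the rest —
# the signature of genes driven by both the circadian and molting clocks.
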