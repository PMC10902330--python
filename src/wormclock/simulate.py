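"""Synthetic time-course expression with planted ground truth.

Generates log2 expression matrices that emulate three sampling designs used
for *C. elegans* clock transcriptomics:

* circadian: 12 timepoints every 4 h, 3 replicates (temperature-cycle
  entrainment followed by constant conditions);
* developmental: 16 timepoints every 1 h, single replicate (L3 to young
  adult, the ~8-h molting clock);
* knockdown: 12 timepoints every 2 h, 2 replicates, two conditions
  (mock vs. hormone-induced depletion of the rhythm driver).

Rhythmic genes follow ``mesor + (amplitude/2) * cos(2*pi*t/period - phase)``
plus i.i.d. Gaussian noise on the log2 scale; arrhythmic genes are mesor
plus noise. The planted parameters are returned as a
:class:`SyntheticTruth` so downstream rhythm detection, clustering and
enrichment can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import (
    DEFAULT_AMPLITUDE_DIST,
    DEFAULT_PHASE_MIXTURE,
    TWO_PI,
    Fixed,
    Uniform,
    WrappedNormalMixture,
)
from .matrix import ExpressionMatrix

TRUTH_COLUMNS = ["is_rhythmic", "period_h", "phase_rad", "amplitude_log2", "mesor", "cluster"]


@dataclass(frozen=True)
class SimulationDesign:
    """Sampling layout and noise model of a synthetic experiment."""

    timepoints: tuple[float, ...]
    replicates_per_timepoint: int = 1
    conditions: tuple[str, ...] = ("main",)
    log2_baseline_mean: float = 6.0
    log2_baseline_sd: float = 1.5
    noise_sd: float = 0.25
    replicate_batch_sd: float = 0.0  # per gene x replicate offset; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0:
            raise ValueError("design needs at least one timepoint")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: sample_id, time_h, condition, replicate."""
        rows = []
        for cond in self.conditions:
            for t in self.timepoints:
                for r in range(1, self.replicates_per_timepoint + 1):
                    sid = f"{cond}_t{t:g}_r{r}"
                    rows.append((sid, float(t), cond, r))
        df = pd.DataFrame(rows, columns=["sample_id", "time_h", "condition", "replicate"])
        return df.set_index("sample_id")


def circadian_design(seed: int = 0, **kw) -> SimulationDesign:
    """12 x 4 h x 3 replicates (adult circadian sampling)."""
    return SimulationDesign(
        timepoints=tuple(float(t) for t in range(0, 48, 4)),
        replicates_per_timepoint=3,
        seed=seed,
        **kw,
    )


def developmental_design(seed: int = 0, **kw) -> SimulationDesign:
    """16 x 1 h x 1 replicate (larval molting-clock sampling)."""
    return SimulationDesign(
        timepoints=tuple(float(t) for t in range(0, 16)),
        replicates_per_timepoint=1,
        seed=seed,
        **kw,
    )


def knockdown_design(seed: int = 0, conditions: tuple[str, str] = ("mock", "auxin"), **kw) -> SimulationDesign:
    """12 x 2 h x 2 replicates x 2 conditions (depletion experiment)."""
    return SimulationDesign(
        timepoints=tuple(float(t) for t in range(0, 24, 2)),
        replicates_per_timepoint=2,
        conditions=conditions,
        seed=seed,
        **kw,
    )


@dataclass
class SyntheticTruth:
    """Planted per-gene rhythm parameters (and, optionally, motif placements).

    ``genes`` is indexed by gene id with columns ``is_rhythmic``,
    ``period_h``, ``phase_rad``, ``amplitude_log2``, ``mesor`` and
    ``cluster`` (phase-peak label for rhythmic genes, ``"none"``
    otherwise). ``condition_amplitude`` maps genes x conditions to the
    amplitude effective in that condition (differs from the base amplitude
    only after a simulated knockdown). ``motif_placements`` is filled by
    the toy-genome generator.
    """

    genes: pd.DataFrame
    design: Optional[SimulationDesign] = None
    condition_amplitude: Optional[pd.DataFrame] = None
    motif_placements: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        g = self.genes
        if (g["amplitude_log2"] < 0).any():
            raise ValueError("planted amplitudes must be >= 0")
        bad = ~g["is_rhythmic"] & (g["amplitude_log2"] != 0)
        if bad.any():
            raise ValueError("non-rhythmic genes must have amplitude 0")
        if ((g["phase_rad"] < 0) | (g["phase_rad"] >= TWO_PI)).any():
            raise ValueError("phases must lie in [0, 2pi)")

    def rhythmic_ids(self) -> list[str]:
        return list(self.genes.index[self.genes["is_rhythmic"]])


def _signal(truth_genes: pd.DataFrame, times: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Noise-free signal matrix, genes x len(times)."""
    period = truth_genes["period_h"].to_numpy(float)
    phase = truth_genes["phase_rad"].to_numpy(float)
    mesor = truth_genes["mesor"].to_numpy(float)
    safe_period = np.where(period > 0, period, 1.0)  # arrhythmic rows masked below
    ang = TWO_PI * times[None, :] / safe_period[:, None] - phase[:, None]
    osc = 0.5 * amplitude[:, None] * np.cos(ang)
    osc[period <= 0] = 0.0
    return mesor[:, None] + osc


def simulate_from_truth(
    design: SimulationDesign,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Render an expression matrix from explicit planted parameters.

    Amplitudes are taken per condition from ``truth.condition_amplitude``
    when present, else from the base column. Noise is drawn from ``rng``
    (default: a fresh generator from ``design.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    samples = design.sample_table()
    n_genes = len(truth.genes)
    values = np.empty((n_genes, len(samples)))
    times_all = samples["time_h"].to_numpy(float)
    for cond in design.conditions:
        mask = (samples["condition"] == cond).to_numpy()
        if truth.condition_amplitude is not None and cond in truth.condition_amplitude.columns:
            amp = truth.condition_amplitude[cond].to_numpy(float)
        else:
            amp = truth.genes["amplitude_log2"].to_numpy(float)
        sig = _signal(truth.genes, times_all[mask], amp)
        noise = rng.normal(0.0, design.noise_sd, size=sig.shape)
        if design.replicate_batch_sd > 0:
            reps = samples.loc[mask, "replicate"].to_numpy()
            offsets = rng.normal(
                0.0, design.replicate_batch_sd, size=(n_genes, reps.max())
            )
            noise += offsets[:, reps - 1]
        values[:, mask] = sig + noise
    df = pd.DataFrame(values, index=truth.genes.index, columns=samples.index)
    return ExpressionMatrix(df, samples)


def simulate_expression(
    design: SimulationDesign,
    n_genes: int,
    frac_rhythmic: float = 0.2,
    period_dist=Fixed(24.0),
    phase_dist: WrappedNormalMixture = DEFAULT_PHASE_MIXTURE,
    amplitude_dist=DEFAULT_AMPLITUDE_DIST,
    cluster_labels: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a matrix with a planted rhythmic fraction.

    Parameters
    ----------
    frac_rhythmic
        Fraction of genes carrying a planted oscillation (rounded to the
        nearest count, chosen at random positions).
    period_dist, phase_dist, amplitude_dist
        Distribution specs for the planted parameters. Negative amplitude
        draws are truncated at 0 by the default spec (documented there).
    cluster_labels
        Names for the phase-mixture components, used as the ``cluster``
        column for rhythmic genes (default ``peak1..peakK``). Arrhythmic
        genes get ``"none"``.

    Returns the matrix and the ground truth. Identical design (including
    seed) and arguments give bitwise-identical output.
    """
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must lie in [0, 1]")
    rng = np.random.default_rng(design.seed)
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    n_rhythmic = int(round(frac_rhythmic * n_genes))
    rhythmic_idx = rng.choice(n_genes, size=n_rhythmic, replace=False)
    is_rhythmic = np.zeros(n_genes, dtype=bool)
    is_rhythmic[rhythmic_idx] = True

    mesor = rng.normal(design.log2_baseline_mean, design.log2_baseline_sd, size=n_genes)
    period = np.zeros(n_genes)
    phase = np.zeros(n_genes)
    amplitude = np.zeros(n_genes)
    cluster = np.array(["none"] * n_genes, dtype=object)
    if n_rhythmic:
        period[is_rhythmic] = period_dist.draw(rng, n_rhythmic)
        ph = phase_dist.draw(rng, n_rhythmic)
        phase[is_rhythmic] = ph
        amplitude[is_rhythmic] = amplitude_dist.draw(rng, n_rhythmic)
        comp = phase_dist.component_labels(ph)
        if cluster_labels is None:
            cluster_labels = [f"peak{i + 1}" for i in range(len(phase_dist.components))]
        cluster[is_rhythmic] = np.array(cluster_labels, dtype=object)[comp]

    genes = pd.DataFrame(
        {
            "is_rhythmic": is_rhythmic,
            "period_h": period,
            "phase_rad": phase,
            "amplitude_log2": amplitude,
            "mesor": mesor,
            "cluster": cluster,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cond_amp = pd.DataFrame(
        {c: genes["amplitude_log2"] for c in design.conditions}, index=genes.index
    )
    truth = SyntheticTruth(genes=genes, design=design, condition_amplitude=cond_amp)
    matrix = simulate_from_truth(design, truth, rng)
    return matrix, truth


def simulate_knockdown(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    target_condition: str,
    amplitude_scale: float,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Scale the oscillatory component of one condition (degron-style ablation).

    The target condition's values are regenerated with every planted
    amplitude multiplied by ``amplitude_scale``; noise for the regenerated
    block is re-drawn from a dedicated stream derived from the stored
    design seed, so the operation is deterministic given the truth object.
    Other conditions are untouched.
    """
    if truth.design is None:
        raise ValueError("truth carries no design; cannot re-draw noise")
    if not 0.0 <= amplitude_scale <= 1.0:
        raise ValueError("amplitude_scale must lie in [0, 1]")
    design = truth.design
    if target_condition not in design.conditions:
        raise KeyError(
            f"unknown condition {target_condition!r}; design has {list(design.conditions)}"
        )
    cond_amp = (
        truth.condition_amplitude.copy()
        if truth.condition_amplitude is not None
        else pd.DataFrame({c: truth.genes["amplitude_log2"] for c in design.conditions})
    )
    cond_amp[target_condition] = cond_amp[target_condition] * amplitude_scale
    new_genes = truth.genes.copy()

    samples = matrix.samples
    mask = (samples["condition"] == target_condition).to_numpy()
    times = samples["time_h"].to_numpy(float)[mask]
    cond_index = list(design.conditions).index(target_condition)
    noise_rng = np.random.default_rng([design.seed, 7919, cond_index])
    sig = _signal(new_genes, times, cond_amp[target_condition].to_numpy(float))
    new_values = matrix.values.copy()
    new_values.loc[:, mask] = sig + noise_rng.normal(0.0, design.noise_sd, size=sig.shape)

    new_truth = SyntheticTruth(
        genes=new_genes,
        design=design,
        condition_amplitude=cond_amp,
        motif_placements=truth.motif_placements,
    )
    return ExpressionMatrix(new_values, samples.copy()), new_truth
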