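"""Phase-binned cis-element enrichment, dual-period overlap and
condition comparison.

Enrichment tests whether genes peaking in one phase bin carry a motif in
their regulatory region more often than the rest of the analysis universe
(other phase peaks plus arrhythmic genes), by a two-sided Fisher exact
test on the presence/absence 2x2 table followed by Holm's step-down
correction across the tested family. The overlap statistic quantifies how
many circadian-rhythmic genes are also rhythmic on the larval ~8-h
(molting) timescale; the condition comparison contrasts rhythm tables of
e.g. mock vs. clock-gene-depleted animals against a time-shuffled null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import OTHER_BIN
from .matrix import ExpressionMatrix
from .rhythm import classify_rhythmic, rhythm_test

ENRICHMENT_COLUMNS = [
    "bin", "motif", "a", "b", "c", "d", "odds_ratio", "p", "p_holm", "empty_bin",
]

DEFAULT_Q_THRESHOLDS = (0.05, 0.10, 0.30)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 count table.

    Extremeness is the probability-mass criterion (tables with
    hypergeometric probability <= that of the observed one, up to a tiny
    relative tolerance for floating-point ties). The returned odds ratio
    is the unconditional sample estimate ``ad/bc`` (inf when ``bc == 0``
    and ``ad > 0``, nan when a margin is zero). A zero margin makes every
    table equally likely, so p = 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return (float("nan"), 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def phase_enrichment(
    bin_assignments: Mapping[str, str] | pd.Series,
    presence: pd.DataFrame,
    universe: Iterable[str],
    motifs: Optional[Sequence[str]] = None,
    background: str = "rest",
    family: str = "all",
    test_bins: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fisher/Holm enrichment of motif presence per phase bin.

    Parameters
    ----------
    bin_assignments
        Gene -> phase-bin label for the rhythmic genes ("other" entries
        are kept as universe members but not tested as a focal bin).
    presence
        Genes x motifs boolean frame (see ``regions.presence_matrix``);
        must cover the universe.
    universe
        All genes in the analysis (rhythmic in any bin + arrhythmic).
    background
        "rest": everything in the universe outside the focal bin
        (other peaks + arrhythmic genes); "arrhythmic": only genes
        carrying no bin assignment.
    family
        "all": Holm across every tested bin x motif pair; "per_motif":
        one family per motif.
    """
    bins = pd.Series(dict(bin_assignments)) if not isinstance(bin_assignments, pd.Series) else bin_assignments
    universe = list(universe)
    uni = pd.Index(universe)
    if uni.has_duplicates:
        raise ValueError("universe contains duplicate gene ids")
    missing = [g for g in bins.index if g not in set(universe)]
    if missing:
        raise ValueError(f"binned genes outside the universe: {missing[:5]}")
    missing_p = [g for g in universe if g not in presence.index]
    if missing_p:
        raise ValueError(f"universe genes absent from the hit table: {missing_p[:5]}")
    if motifs is None:
        motifs = list(presence.columns)
    if background not in ("rest", "arrhythmic"):
        raise ValueError("background must be 'rest' or 'arrhythmic'")

    pres = presence.loc[universe, motifs].astype(bool)
    binned = set(bins.index)
    if test_bins is not None:
        focal_bins = list(test_bins)  # a requested bin may be empty: flagged below
    else:
        focal_bins = [b for b in dict.fromkeys(bins.values) if b != OTHER_BIN]
    rows = []
    for bin_label in focal_bins:
        members = [g for g in universe if g in binned and bins[g] == bin_label]
        if background == "rest":
            bg = [g for g in universe if g not in set(members)]
        else:
            bg = [g for g in universe if g not in binned]
        for motif in motifs:
            if not members:
                rows.append((bin_label, motif, 0, 0, 0, 0, float("nan"), 1.0, True))
                continue
            in_with = int(pres.loc[members, motif].sum())
            in_without = len(members) - in_with
            bg_with = int(pres.loc[bg, motif].sum())
            bg_without = len(bg) - bg_with
            odds, p = fisher_exact_2x2([[in_with, in_without], [bg_with, bg_without]])
            rows.append((bin_label, motif, in_with, in_without, bg_with, bg_without, odds, p, False))
    out = pd.DataFrame(
        rows, columns=["bin", "motif", "a", "b", "c", "d", "odds_ratio", "p", "empty_bin"]
    )
    if family == "all":
        out["p_holm"] = holm_adjust(out["p"]) if len(out) else []
    elif family == "per_motif":
        out["p_holm"] = np.nan
        for motif in motifs:
            sel = out["motif"] == motif
            out.loc[sel, "p_holm"] = holm_adjust(out.loc[sel, "p"])
    else:
        raise ValueError("family must be 'all' or 'per_motif'")
    return out[ENRICHMENT_COLUMNS]


@dataclass
class OverlapResult:
    """Overlap of circadian- and developmental-rhythmic gene sets."""

    universe_size: int
    circadian_size: int
    developmental_size: int
    intersection_size: int
    proportion: float  # of circadian genes that are also developmental
    p_hypergeom: float  # over-representation of the intersection
    per_bin: dict[str, dict[str, float]] = field(default_factory=dict)
    undefined: bool = False  # circadian set empty

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "circadian_size": self.circadian_size,
            "developmental_size": self.developmental_size,
            "intersection_size": self.intersection_size,
            "proportion": self.proportion,
            "p_hypergeom": self.p_hypergeom,
            "per_bin": self.per_bin,
            "undefined": self.undefined,
        }


def dual_period_overlap(
    circadian: Iterable[str],
    developmental: Iterable[str],
    universe: Iterable[str],
    bins: Optional[Mapping[str, str] | pd.Series] = None,
) -> OverlapResult:
    """Proportion of circadian genes that are also developmentally rhythmic.

    The over-representation p-value is the hypergeometric upper tail of
    the intersection size given the universe. With ``bins`` (gene ->
    phase-bin for circadian genes) per-bin proportions are reported too.
    """
    uni = set(universe)
    circ = set(circadian)
    dev = set(developmental)
    if not circ <= uni or not dev <= uni:
        raise ValueError("gene sets must be subsets of the universe")
    inter = circ & dev
    if not circ:
        return OverlapResult(len(uni), 0, len(dev), 0, float("nan"), 1.0, {}, undefined=True)
    M, K, n, k = len(uni), len(dev), len(circ), len(inter)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    per_bin: dict[str, dict[str, float]] = {}
    if bins is not None:
        bins = pd.Series(dict(bins)) if not isinstance(bins, pd.Series) else bins
        for label in dict.fromkeys(bins.values):
            members = {g for g in circ if bins.get(g) == label}
            if members:
                per_bin[label] = {
                    "size": len(members),
                    "overlap": len(members & dev),
                    "proportion": len(members & dev) / len(members),
                }
    return OverlapResult(
        universe_size=M,
        circadian_size=n,
        developmental_size=K,
        intersection_size=k,
        proportion=k / n,
        p_hypergeom=p,
        per_bin=per_bin,
    )


def _shuffle_times(matrix: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Permute timepoint labels, replicate blocks intact, per condition."""
    samples = matrix.samples.copy()
    for cond in matrix.conditions():
        mask = samples["condition"] == cond
        t = samples.loc[mask, "time_h"].to_numpy(float)
        uniq = np.unique(t)
        perm = uniq[rng.permutation(uniq.size)]
        samples.loc[mask, "time_h"] = perm[np.searchsorted(uniq, t)]
    return ExpressionMatrix(matrix.values.copy(), samples)


def shuffle_null(
    matrix: ExpressionMatrix,
    n_shuffles: int = 20,
    seed: int = 0,
    q_thresholds: Sequence[float] = DEFAULT_Q_THRESHOLDS,
    **rhythm_settings,
) -> pd.DataFrame:
    """Rhythmic-gene counts after repeated time shuffling (empirical null).

    Each shuffle permutes which sampling time each timepoint block
    carries, reruns the full rhythm test (with its own derived seed) and
    records the number of genes below each q threshold. Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rhythm_settings.pop("seed", None)  # each shuffle gets its own derived seed
    rows = []
    for i in range(n_shuffles):
        shuffled = _shuffle_times(matrix, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = rhythm_test(shuffled, seed=sub_seed, **rhythm_settings)
        rows.append([int((table["q"] < qt).sum()) for qt in q_thresholds])
    return pd.DataFrame(rows, columns=[f"q_lt_{qt:g}" for qt in q_thresholds])


@dataclass
class ConditionComparison:
    """Per-condition rhythm tables, counts and per-gene loss flags."""

    condition_a: str
    condition_b: str
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    counts: pd.DataFrame  # conditions x q thresholds
    lost: pd.Series  # rhythmic in a, not rhythmic in b

    def n_lost(self) -> int:
        return int(self.lost.sum())


def compare_conditions(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    q_threshold: float = 0.30,
    amplitude_threshold: float = 0.0,
    q_thresholds: Sequence[float] = DEFAULT_Q_THRESHOLDS,
    **rhythm_settings,
) -> ConditionComparison:
    """Independent rhythm tables per condition plus rhythm-loss flags.

    A gene is flagged ``lost`` when it passes (q, amplitude) thresholds in
    condition a but not in condition b. BH correction is applied within
    each condition separately.
    """
    for cond in (condition_a, condition_b):
        if cond not in matrix.conditions():
            raise KeyError(f"condition {cond!r} not in matrix ({matrix.conditions()})")
    table_a = rhythm_test(matrix.subset_condition(condition_a), **rhythm_settings)
    table_b = rhythm_test(matrix.subset_condition(condition_b), **rhythm_settings)
    set_a = classify_rhythmic(table_a, q_threshold, amplitude_threshold)
    set_b = classify_rhythmic(table_b, q_threshold, amplitude_threshold)
    lost = pd.Series(
        [g in set_a and g not in set_b for g in matrix.gene_ids],
        index=matrix.values.index,
        name="lost",
    )
    counts = pd.DataFrame(
        {
            f"q_lt_{qt:g}": [
                int((table_a["q"] < qt).sum()),
                int((table_b["q"] < qt).sum()),
            ]
            for qt in q_thresholds
        },
        index=[condition_a, condition_b],
    )
    return ConditionComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        table_a=table_a,
        table_b=table_b,
        counts=counts,
        lost=lost,
    )
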