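"""Rhythm detection by cosinor fitting over a period window.

The periodicity statistic is the variance explained by the best
single-cosine (cosinor) fit across a grid of candidate periods,
``1 - rss_best / rss_intercept``. Its null distribution is obtained by
permuting timepoint labels with replicate blocks kept intact (the same
permutations for all genes), and p-values are Benjamini-Hochberg adjusted
across genes. Parameter estimates come from the exact least-squares
solution of ``y = m + a*cos(2*pi*t/T) + b*sin(2*pi*t/T)``:

* mesor ``m`` (rhythm-adjusted mean, log2 units),
* amplitude ``2*sqrt(a^2 + b^2)`` — peak-to-trough on the log2 scale, so
  amplitude 1 is approximately a 2-fold change (``half_range`` selects
  ``sqrt(a^2+b^2)`` instead),
* phase ``atan2(b, a) mod 2pi`` — the peak position in radians relative to
  t = 0 of the analyzed segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

TWO_PI = 2.0 * np.pi
AMPLITUDE_TOL = 1e-9

#: supported amplitude conventions -> multiplier of sqrt(a^2 + b^2)
AMPLITUDE_CONVENTIONS = {"peak_to_trough": 2.0, "half_range": 1.0}

RHYTHM_TABLE_COLUMNS = [
    "period_h",
    "mesor",
    "amplitude_log2",
    "phase_rad",
    "rss",
    "p_raw",
    "q",
    "rhythmic",
]


class DegenerateDesignError(ValueError):
    """Raised when the cosinor design matrix is rank-deficient."""


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares single-cosine fit at one period."""

    period: float
    mesor: float
    amplitude: float  # peak-to-trough, log2 units (by default convention)
    phase: float  # radians in [0, 2pi), peak position
    rss: float


def _design_matrix(times: np.ndarray, period: float) -> np.ndarray:
    ang = TWO_PI * times / period
    return np.column_stack([np.ones_like(times), np.cos(ang), np.sin(ang)])


def fit_cosinor(
    values,
    times,
    period: float,
    amplitude_convention: str = "peak_to_trough",
) -> CosinorFit:
    """Exact least-squares cosinor fit at a single period.

    Requires >= 4 observations at >= 3 distinct times; replicates enter as
    independent observations. Raises :class:`DegenerateDesignError` when
    the design is rank-deficient (e.g. the period aliases the sampling
    grid so the sine column vanishes).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    if period <= 0:
        raise ValueError("period must be positive")
    if y.size < 4 or np.unique(t).size < 3:
        raise DegenerateDesignError(
            f"need >= 4 observations at >= 3 distinct times, got {y.size} at {np.unique(t).size}"
        )
    X = _design_matrix(t, period)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise DegenerateDesignError(f"rank-deficient cosinor design at period {period}")
    resid = y - X @ beta
    rss = float(resid @ resid)
    mult = AMPLITUDE_CONVENTIONS[amplitude_convention]
    m, a, b = beta
    r = float(np.hypot(a, b))
    if mult * r < AMPLITUDE_TOL:
        amplitude, phase = 0.0, 0.0
    else:
        amplitude = mult * r
        phase = float(np.mod(np.arctan2(b, a), TWO_PI))
    return CosinorFit(period=float(period), mesor=float(m), amplitude=amplitude, phase=phase, rss=rss)


def period_grid(period_min: float, period_max: float, period_step: float = 0.5) -> np.ndarray:
    if period_min > period_max:
        raise ValueError("period_min must be <= period_max")
    if period_step <= 0:
        raise ValueError("period_step must be positive")
    n = int(np.floor((period_max - period_min) / period_step + 1e-9))
    grid = period_min + period_step * np.arange(n + 1)
    if grid.size == 0:
        raise ValueError("empty period grid")
    return grid


def scan_periods(
    values,
    times,
    period_min: float,
    period_max: float,
    period_step: float = 0.5,
    amplitude_convention: str = "peak_to_trough",
) -> CosinorFit:
    """Best cosinor fit (minimal rss) over the period grid.

    Ties are broken toward the shortest period: the grid is scanned in
    ascending order and only improvements beyond a small tolerance
    (relative to the series' total sum of squares) replace the incumbent.
    """
    y = np.asarray(values, dtype=float)
    tol = 1e-9 * (float(y @ y) + 1.0)
    best: CosinorFit | None = None
    for p in period_grid(period_min, period_max, period_step):
        fit = fit_cosinor(values, times, p, amplitude_convention)
        if best is None or fit.rss < best.rss - tol:
            best = fit
    assert best is not None
    return best


def _projection_rss(Q: np.ndarray, Y: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """Residual sums of squares for all genes given an orthonormal basis Q.

    ``Y`` is genes x samples, ``sumsq`` its per-gene squared norms;
    rss = ||y||^2 - ||Q^T y||^2.
    """
    C = Q.T @ Y.T  # 3 x genes
    return np.maximum(sumsq - np.einsum("ij,ij->j", C, C), 0.0)


def rhythm_test(
    matrix: ExpressionMatrix,
    period_min: float,
    period_max: float,
    period_step: float = 0.5,
    n_permutations: int = 999,
    seed: int | None = 0,
    q_threshold: float = 0.10,
    amplitude_threshold: float = 1.0,
    amplitude_convention: str = "peak_to_trough",
) -> pd.DataFrame:
    """Permutation test for periodicity within a period window.

    Returns the rhythm table: per gene the best-grid-period cosinor
    parameters, the permutation p-value
    ``(1 + #{permuted stat >= observed}) / (1 + n_permutations)``, the BH
    q-value across genes, and the ``rhythmic`` flag
    ``q < q_threshold and amplitude > amplitude_threshold``.

    Permutations shuffle which sampling time each timepoint block carries,
    keeping replicates of a timepoint together; the identical permutation
    sequence is applied to every gene so gene statistics share a null.
    """
    conds = matrix.conditions()
    if len(conds) > 1:
        raise ValueError(
            f"matrix mixes conditions {conds}; subset_condition() first — the"
            " multiple-testing correction is per analysis run"
        )
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    t = matrix.times()
    uniq = np.unique(t)
    if uniq.size < 8:
        raise ValueError(
            f"need >= 8 distinct timepoints for the periodicity test, got {uniq.size}"
        )
    grid = period_grid(period_min, period_max, period_step)
    Y = matrix.values.to_numpy(dtype=float)
    n_genes = Y.shape[0]
    Ym = Y.mean(axis=1, keepdims=True)
    Yc = Y - Ym
    sumsq = np.einsum("ij,ij->i", Yc, Yc)  # intercept-only rss
    rss0 = sumsq.copy()

    # observed fits: track best rss and its period per gene
    tc = t  # times as given; default designs start at 0 h
    qs = [np.linalg.qr(_design_matrix(tc, p), mode="reduced")[0] for p in grid]
    best_rss = np.full(n_genes, np.inf)
    best_period_idx = np.zeros(n_genes, dtype=int)
    tie_tol = 1e-9 * (sumsq + 1.0)  # shortest period wins numerical ties
    for i, Q in enumerate(qs):
        rss = _projection_rss(Q, Yc, sumsq)
        better = rss < best_rss - tie_tol
        best_rss[better] = rss[better]
        best_period_idx[better] = i
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(rss0 > 0, 1.0 - best_rss / rss0, 0.0)

    # permutation null: same timepoint-label shuffles for every gene
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_genes, dtype=np.int64)
    group_of_sample = np.searchsorted(uniq, t)
    for _ in range(n_permutations):
        perm_times = uniq[rng.permutation(uniq.size)][group_of_sample]
        perm_best = np.full(n_genes, np.inf)
        for p in grid:
            Q = np.linalg.qr(_design_matrix(perm_times, p), mode="reduced")[0]
            np.minimum(perm_best, _projection_rss(Q, Yc, sumsq), out=perm_best)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_stat = np.where(rss0 > 0, 1.0 - perm_best / rss0, 0.0)
        exceed += perm_stat >= stat
    p_raw = (1.0 + exceed) / (1.0 + n_permutations)
    q = multipletests(p_raw, method="fdr_bh")[1]

    # coefficients at each gene's best period
    mesor = np.empty(n_genes)
    amplitude = np.empty(n_genes)
    phase = np.empty(n_genes)
    mult = AMPLITUDE_CONVENTIONS[amplitude_convention]
    for i, p in enumerate(grid):
        sel = best_period_idx == i
        if not sel.any():
            continue
        X = _design_matrix(tc, p)
        beta, _, _, _ = np.linalg.lstsq(X, Y[sel].T, rcond=None)
        mesor[sel] = beta[0]
        r = np.hypot(beta[1], beta[2])
        amp = mult * r
        ph = np.mod(np.arctan2(beta[2], beta[1]), TWO_PI)
        ph[amp < AMPLITUDE_TOL] = 0.0
        amp[amp < AMPLITUDE_TOL] = 0.0
        amplitude[sel] = amp
        phase[sel] = ph

    table = pd.DataFrame(
        {
            "period_h": grid[best_period_idx],
            "mesor": mesor,
            "amplitude_log2": amplitude,
            "phase_rad": phase,
            "rss": best_rss,
            "p_raw": p_raw,
            "q": q,
            "rhythmic": (q < q_threshold) & (amplitude > amplitude_threshold),
        },
        index=matrix.values.index.copy(),
    )
    table.index.name = "gene_id"
    return table


def classify_rhythmic(
    table: pd.DataFrame, q_threshold: float = 0.10, amplitude_threshold: float = 1.0
) -> set[str]:
    """Genes with ``q < q_threshold`` and ``amplitude > amplitude_threshold``.

    Both comparisons are strict: an amplitude of exactly the threshold does
    not qualify (the selection "q < 0.10 with 1 < amplitude").
    """
    if not 0.0 < q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in (0, 1]")
    if amplitude_threshold < 0:
        raise ValueError("amplitude_threshold must be >= 0")
    if table.empty:
        return set()
    sel = (table["q"] < q_threshold) & (table["amplitude_log2"] > amplitude_threshold)
    return set(table.index[sel])
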