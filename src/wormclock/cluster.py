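"""Waveform clustering and phase binning of rhythmic genes.

Rhythmic genes are grouped by the similarity of their (amplitude-
normalized) temporal profiles under cosine distance with agglomerative
clustering, and assigned to configurable phase bins. The default bins are
the three phase peaks observed in temperature-entrained adult worms:
[pi/6, pi/2) ("magenta", the ROR/NHR-23-driven peak), [pi/2, 5pi/6)
("navy") and [4pi/3, 5pi/3) ("gray"); phases outside every bin map to
"other" so the assignment is total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

TWO_PI = 2.0 * np.pi

OTHER_BIN = "other"


class PhaseBinConfigError(ValueError):
    """Raised for overlapping or malformed phase-bin configurations."""


@dataclass(frozen=True)
class PhaseBin:
    """Half-open phase interval [lower, upper) in radians."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= TWO_PI):
            raise PhaseBinConfigError(
                f"bin {self.label!r}: need 0 <= lower < upper <= 2pi, got "
                f"[{self.lower}, {self.upper})"
            )

    def contains(self, phase: float) -> bool:
        return self.lower <= phase < self.upper


DEFAULT_PHASE_BINS: tuple[PhaseBin, ...] = (
    PhaseBin("magenta", np.pi / 6.0, np.pi / 2.0),
    PhaseBin("navy", np.pi / 2.0, 5.0 * np.pi / 6.0),
    PhaseBin("gray", 4.0 * np.pi / 3.0, 5.0 * np.pi / 3.0),
)


def validate_bins(bins: Sequence[PhaseBin]) -> None:
    ordered = sorted(bins, key=lambda b: b.lower)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.lower < prev.upper:
            raise PhaseBinConfigError(
                f"bins {prev.label!r} and {nxt.label!r} overlap"
            )


def normalize_profile(values, mode: str = "amplitude") -> np.ndarray:
    """Normalize a temporal profile.

    ``amplitude`` mode mean-centers and scales to unit Euclidean norm (the
    normalization applied before waveform clustering); a constant series is
    an error. ``minmax`` mode maps to [0, 1] (max = 1, min = 0, the scaling
    used for knockdown heatmap comparisons); a constant series maps to all
    zeros by convention.
    """
    x = np.asarray(values, dtype=float)
    if mode == "amplitude":
        c = x - x.mean()
        norm = float(np.linalg.norm(c))
        if norm == 0.0:
            raise ValueError("constant series cannot be amplitude-normalized")
        return c / norm
    if mode == "minmax":
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown normalization mode {mode!r}")


def cosine_distance(x, y) -> float:
    """``1 - x.y / (|x| |y|)``, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (x @ y) / (nx * ny))


@dataclass
class ClusterAssignment:
    """Gene -> cluster label (1..k) plus the linkage matrix for audit."""

    labels: pd.Series
    linkage_matrix: np.ndarray
    n_clusters: int

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def hierarchical_cluster(
    profiles: pd.DataFrame, n_clusters: int, method: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of gene profiles under cosine distance.

    ``profiles`` is genes x timepoints (normalize rows first for waveform
    clustering). Deterministic given input order; scipy's linkage resolves
    merge-height ties toward the lowest-index pair.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if len(profiles) < n_clusters:
        raise ValueError(
            f"cannot cut {len(profiles)} genes into {n_clusters} clusters"
        )
    dist = pdist(profiles.to_numpy(dtype=float), metric="cosine")
    Z = linkage(dist, method=method)
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=profiles.index, name="cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=Z, n_clusters=n_clusters)


def assign_phase_bin(phase: float, bins: Sequence[PhaseBin] = DEFAULT_PHASE_BINS) -> str:
    """Label of the unique half-open bin containing ``phase``, else "other"."""
    if not 0.0 <= phase < TWO_PI:
        raise ValueError(f"phase must lie in [0, 2pi), got {phase}")
    validate_bins(bins)
    for b in bins:
        if b.contains(phase):
            return b.label
    return OTHER_BIN


def assign_phase_bins(
    phases: pd.Series, bins: Sequence[PhaseBin] = DEFAULT_PHASE_BINS
) -> pd.Series:
    """Vectorized bin assignment for a gene -> phase series."""
    validate_bins(bins)
    out = pd.Series(OTHER_BIN, index=phases.index, dtype=object, name="bin")
    ph = phases.to_numpy(dtype=float)
    if ((ph < 0) | (ph >= TWO_PI)).any():
        raise ValueError("phases must lie in [0, 2pi)")
    for b in bins:
        out[(ph >= b.lower) & (ph < b.upper)] = b.label
    return out


def phase_histogram(phases: Iterable[float], n_bins: int = 12) -> pd.DataFrame:
    """Counts over equal-width bins covering [0, 2pi)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ph = np.asarray(list(phases), dtype=float)
    counts, edges = np.histogram(ph, bins=n_bins, range=(0.0, TWO_PI))
    return pd.DataFrame(
        {"lower": edges[:-1], "upper": edges[1:], "count": counts}
    )
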