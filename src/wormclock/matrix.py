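"""Expression-matrix container shared by every analysis stage.

A :class:`ExpressionMatrix` holds a log2-scale genes x samples table plus
per-sample metadata (sampling time in hours, condition label, replicate
index). On the log2 scale a fitted peak-to-trough amplitude of 1
corresponds approximately to a 2-fold change, which is the calibration the
downstream rhythmicity thresholds rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_SAMPLE_COLUMNS = ("time_h", "condition", "replicate")


class MatrixValidationError(ValueError):
    """Raised when an expression matrix violates its contract."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``time_h`` (hours,
        float), ``condition`` (label) and ``replicate`` (int). Row order
        must match the column order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene ids: {dups[:5]}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise MatrixValidationError(f"sample metadata lacks column {col!r}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise MatrixValidationError(f"samples missing from metadata: {missing}")
        orphan = [s for s in self.samples.index if s not in self.values.columns]
        if orphan:
            raise MatrixValidationError(f"metadata samples absent from matrix: {orphan}")
        # align metadata rows to matrix column order
        self.samples = self.samples.loc[list(self.values.columns)]
        if self.samples["time_h"].isna().any():
            bad = self.samples.index[self.samples["time_h"].isna()].tolist()
            raise MatrixValidationError(f"samples without a time: {bad}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise MatrixValidationError(
                "non-finite expression value at gene "
                f"{self.values.index[gi]!r}, sample {self.values.columns[si]!r}"
            )

    # -- accessors --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        """Sampling time of each column, hours."""
        return self.samples["time_h"].to_numpy(dtype=float)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        """Restrict to samples of one condition (new object)."""
        if condition not in set(self.samples["condition"]):
            raise KeyError(f"condition {condition!r} not present; have {self.conditions()}")
        keep = self.samples.index[self.samples["condition"] == condition]
        return ExpressionMatrix(self.values[list(keep)].copy(), self.samples.loc[keep].copy())

    def subset_times(self, t_min: float, t_max: float) -> "ExpressionMatrix":
        """Restrict to samples with ``t_min <= time_h <= t_max`` (e.g. to
        analyze only the free-running segment of an entrainment design)."""
        keep = self.samples.index[
            (self.samples["time_h"] >= t_min) & (self.samples["time_h"] <= t_max)
        ]
        if len(keep) == 0:
            raise ValueError(f"no samples in time window [{t_min}, {t_max}]")
        return ExpressionMatrix(self.values[list(keep)].copy(), self.samples.loc[keep].copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.samples.copy())

    def mean_profiles(self) -> pd.DataFrame:
        """Replicate-averaged profiles: genes x sorted unique timepoints.

        Columns are the distinct ``time_h`` values; replicates (and, if the
        matrix mixes conditions, conditions sharing a timepoint) are
        averaged. This is the per-gene row that phase clustering consumes.
        """
        t = self.times()
        order = np.argsort(np.unique(t))
        uniq = np.unique(t)[order]
        cols = {u: self.values.loc[:, t == u].mean(axis=1) for u in uniq}
        return pd.DataFrame(cols, index=self.values.index)
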