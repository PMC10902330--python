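"""Pipeline configuration: one YAML-serializable object, hashed for audit.

The defaults encode the analysis settings of the adult-circadian study
design: a 20-28 h period window for the adult analysis and 8-10 h for the
larval (molting) analysis, BH q and amplitude thresholds 0.05 (strict),
0.10 with amplitude > 1 (phase-distribution set) and 0.30 (low-power
knockdown comparison), the three phase bins, the RORE/D-box/E-box motif
set and a 4 kb upstream window.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cluster import DEFAULT_PHASE_BINS, PhaseBin, validate_bins
from .regions import DEFAULT_MOTIFS, DEFAULT_UPSTREAM_LENGTH, MotifDef


@dataclass
class PipelineConfig:
    # period windows, hours
    circadian_period_min: float = 20.0
    circadian_period_max: float = 28.0
    developmental_period_min: float = 8.0
    developmental_period_max: float = 10.0
    period_step: float = 0.5
    # selection thresholds
    q_strict: float = 0.05
    q_phase: float = 0.10
    amplitude_phase: float = 1.0
    q_loose: float = 0.30
    # phase bins / motifs
    phase_bins: tuple[PhaseBin, ...] = DEFAULT_PHASE_BINS
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS
    upstream_length: int = DEFAULT_UPSTREAM_LENGTH
    # testing
    n_permutations: int = 999
    seed: int = 0
    background: str = "rest"
    n_clusters: int = 4
    # synthetic-run sizes (used when no input paths are given)
    n_genes: int = 1000
    frac_rhythmic: float = 0.2
    noise_sd: float = 0.25
    # optional input paths (real-data mode)
    expression_path: Optional[str] = None
    metadata_path: Optional[str] = None
    fasta_path: Optional[str] = None
    gff3_path: Optional[str] = None

    def __post_init__(self) -> None:
        validate_bins(self.phase_bins)
        for q in (self.q_strict, self.q_phase, self.q_loose):
            if not 0.0 < q <= 1.0:
                raise ValueError(f"q threshold {q} outside (0, 1]")
        if self.circadian_period_min > self.circadian_period_max:
            raise ValueError("circadian period window inverted")
        if self.developmental_period_min > self.developmental_period_max:
            raise ValueError("developmental period window inverted")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        for p in (self.expression_path, self.metadata_path, self.fasta_path, self.gff3_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_bins"] = [
            {"label": b.label, "lower": b.lower, "upper": b.upper} for b in self.phase_bins
        ]
        d["motifs"] = [{"name": m.name, "iupac": m.iupac} for m in self.motifs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phase_bins" in d:
            d["phase_bins"] = tuple(
                PhaseBin(b["label"], float(b["lower"]), float(b["upper"]))
                for b in d["phase_bins"]
            )
        if "motifs" in d:
            d["motifs"] = tuple(MotifDef(m["name"], m["iupac"]) for m in d["motifs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash over analysis-relevant fields (paths excluded)."""
        d = self.to_dict()
        for key in ("expression_path", "metadata_path", "fasta_path", "gff3_path"):
            d.pop(key, None)
        canon = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
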