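"""Toy genomes with motifs planted in known regulatory regions.

Builds random background sequence, lays out multi-exon gene models and —
per gene, with a probability set by the gene's phase-cluster label —
writes one concrete expansion of an IUPAC motif at a uniformly chosen
position of the gene's regulatory region (4 kb upstream + introns). The
placement truth is recorded so cis-element enrichment can be scored
against a planted answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .regions import (
    DEFAULT_UPSTREAM_LENGTH,
    GeneModel,
    IUPAC_CODES,
    MotifDef,
    reverse_complement,
)
from .simulate import SyntheticTruth

BASES = "ACGT"


@dataclass(frozen=True)
class GeneSpec:
    """Layout request for one gene on the toy genome."""

    gene_id: str
    cluster: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.contig, self.strand, self.exons)


def make_gene_specs(
    clusters: Sequence[str],
    gene_ids: Optional[Sequence[str]] = None,
    n_exons: int = 3,
    exon_length: int = 200,
    intron_length: int = 300,
    upstream_length: int = DEFAULT_UPSTREAM_LENGTH,
    spacing: int = 500,
    contig: str = "toy_chr1",
) -> list[GeneSpec]:
    """Lay genes left-to-right on one contig, strands alternating.

    Consecutive genes are separated by at least ``upstream_length +
    spacing`` so regulatory regions never collide.
    """
    specs = []
    cursor = 0
    for i, cl in enumerate(clusters):
        gid = gene_ids[i] if gene_ids is not None else f"g{i + 1:05d}"
        strand = "+" if i % 2 == 0 else "-"
        start = cursor + upstream_length
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((pos, pos + exon_length))
            pos += exon_length + intron_length
        end = exons[-1][1]
        specs.append(GeneSpec(gid, cl, contig, strand, tuple(exons)))
        cursor = end + upstream_length + spacing
    return specs


def _expand_iupac(motif: MotifDef, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in motif.iupac)


def simulate_genome(
    gene_specs: Sequence[GeneSpec],
    motifs: Sequence[MotifDef],
    placement_probs: Mapping[str, float],
    background_base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    upstream_length: int = DEFAULT_UPSTREAM_LENGTH,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Random genome with cluster-dependent motif planting.

    For each gene and motif, with probability
    ``placement_probs.get(cluster, 0)`` a single concrete expansion of the
    motif (uniform over allowed bases, uniform strand) is written at a
    uniformly chosen valid start position across the gene's regulatory
    parts. Placements never overlap each other; chance background matches
    may of course also occur. Returns the genome (contig -> sequence),
    the gene models, and a truth object whose ``motif_placements`` frame
    has one row per planted instance (gene_id, motif, contig, start,
    strand) and whose ``genes`` frame records the cluster labels.
    """
    probs = np.asarray(background_base_probs, dtype=float)
    if probs.size != 4 or not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
        raise ValueError("background_base_probs must be 4 non-negative values summing to 1")
    for cl, p in placement_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"placement probability for {cl!r} out of [0, 1]")
    rng = np.random.default_rng(seed)

    # contig lengths: cover every gene (+ room for a trailing upstream region)
    contig_len: dict[str, int] = {}
    by_contig: dict[str, list[GeneSpec]] = {}
    for spec in gene_specs:
        model = spec.model()
        need = model.end + upstream_length
        contig_len[spec.contig] = max(contig_len.get(spec.contig, 0), need)
        by_contig.setdefault(spec.contig, []).append(spec)
    for contig, specs in by_contig.items():
        ivs = sorted((s.model().start, s.model().end, s.gene_id) for s in specs)
        for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"gene layouts overlap on {contig}: {g1}, {g2}")

    base_bytes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    if np.allclose(probs, 0.25):  # uniform draw avoids the slower p-weighted path
        genome_arrays = {
            c: base_bytes[rng.integers(0, 4, size=n)] for c, n in contig_len.items()
        }
    else:
        genome_arrays = {
            c: rng.choice(base_bytes, size=n, p=probs) for c, n in contig_len.items()
        }

    models = [spec.model() for spec in gene_specs]
    placements = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for spec, model in zip(gene_specs, models):
        clen = contig_len[spec.contig]
        parts = [model.upstream_interval(clen, upstream_length), *model.introns()]
        for motif in motifs:
            p = placement_probs.get(spec.cluster, 0.0)
            if rng.random() >= p:
                continue
            m = len(motif)
            starts = [(s, e) for (s, e) in parts if e - s >= m]
            if not starts:
                raise ValueError(
                    f"{spec.gene_id}: motif {motif.name} ({m} bp) longer than every regulatory part"
                )
            weights = np.array([e - s - m + 1 for (s, e) in starts], dtype=float)
            taken = occupied.setdefault(spec.gene_id, [])
            pos = None
            for _ in range(100):  # resample on collision with a prior placement
                part = starts[rng.choice(len(starts), p=weights / weights.sum())]
                cand = int(part[0] + rng.integers(0, part[1] - part[0] - m + 1))
                if all(cand + m <= a or cand >= b for (a, b) in taken):
                    pos = cand
                    break
            if pos is None:
                raise RuntimeError(f"{spec.gene_id}: could not place {motif.name} without collision")
            taken.append((pos, pos + m))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _expand_iupac(motif, rng)
            written = instance if strand == "+" else reverse_complement(instance)
            genome_arrays[spec.contig][pos : pos + m] = np.frombuffer(
                written.encode(), dtype=np.uint8
            )
            placements.append((spec.gene_id, motif.name, spec.contig, pos, strand))

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}
    placement_df = pd.DataFrame(
        placements, columns=["gene_id", "motif", "contig", "start", "strand"]
    )
    # genome truth tracks clusters/placements only, not expression parameters
    genes_df = pd.DataFrame(
        {
            "is_rhythmic": False,
            "period_h": 0.0,
            "phase_rad": 0.0,
            "amplitude_log2": 0.0,
            "mesor": 0.0,
            "cluster": [s.cluster for s in gene_specs],
        },
        index=pd.Index([s.gene_id for s in gene_specs], name="gene_id"),
    )
    truth = SyntheticTruth(genes=genes_df, motif_placements=placement_df)
    return genome, models, truth


def planted_counts(truth: SyntheticTruth, motif_name: str) -> pd.Series:
    """Planted instances per gene for one motif (0 for genes without any)."""
    if truth.motif_placements is None:
        raise ValueError("truth has no motif placements")
    mp = truth.motif_placements
    counts = mp[mp["motif"] == motif_name].groupby("gene_id").size()
    return counts.reindex(truth.genes.index, fill_value=0)
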