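"""Regulatory-region extraction and degenerate (IUPAC) motif scanning.

A gene's regulatory region is defined as the 4 kb upstream of its first
exon (strand-aware, truncated at contig boundaries) plus all of its
introns. Motifs are IUPAC consensus strings — e.g. the ROR response
element RORE, ``WAWNTRGGTCA`` — scanned on both strands with overlapping
matches counted. Enrichment downstream uses only per-gene presence/absence,
so the overlap and double-strand conventions cannot change a presence call.

Internal coordinates are 0-based half-open; GFF3 I/O (in :mod:`.io`)
converts from the standard's 1-based inclusive intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_UPSTREAM_LENGTH = 4000

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: cis-elements tested by default: RORE plus the other clock elements
#: (D-box and E/E'-box consensus strings are package defaults, configurable).
DEFAULT_MOTIFS: tuple["MotifDef", ...] = ()  # filled below


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """Named IUPAC consensus motif."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("motif string must be non-empty")
        bad = [c for c in self.iupac.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC codes in {self.iupac!r}: {bad}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


DEFAULT_MOTIFS = (
    MotifDef("RORE", "WAWNTRGGTCA"),
    MotifDef("D-box", "TTATGYAA"),
    MotifDef("E-box", "CACGTG"),
    MotifDef("Ep-box", "CACGTT"),
)


def iupac_match_probability(motif: MotifDef, base_probs: Mapping[str, float]) -> float:
    """Per-position match probability of ``motif`` against i.i.d. bases.

    Product over motif positions of the summed probabilities of the
    allowed bases; e.g. RORE under uniform bases is
    ``(1/2)^3 * (1/4)^7 = 7.629e-06`` per position per strand.
    """
    total = sum(base_probs.get(b, 0.0) for b in "ACGT")
    if not np.isclose(total, 1.0):
        raise ValueError(f"base probabilities must sum to 1, got {total}")
    p = 1.0
    for code in motif.iupac:
        p *= sum(base_probs.get(b, 0.0) for b in IUPAC_CODES[code])
    return p


# -- scanning ------------------------------------------------------------

_BASE_INDEX = np.full(128, 5, dtype=np.uint8)  # 5 = unknown, never matches
for _i, _b in enumerate("ACGTN"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def _allowed_table(motif: MotifDef) -> np.ndarray:
    """Boolean table (motif position x base A,C,G,T,N,other)."""
    table = np.zeros((len(motif.iupac), 6), dtype=bool)
    for j, code in enumerate(motif.iupac):
        for b in IUPAC_CODES[code]:
            table[j, "ACGT".index(b)] = True
        if code == "N":  # an ambiguous genome base satisfies only code N
            table[j, 4] = True
    return table


@dataclass(frozen=True)
class MotifHits:
    """Match count and (position, strand) list for one sequence scan."""

    count: int
    positions: tuple[tuple[int, str], ...] = field(default=())


def _scan_strand(seq_idx: np.ndarray, table: np.ndarray) -> np.ndarray:
    m = table.shape[0]
    n = seq_idx.size
    if n < m:
        return np.zeros(0, dtype=bool)
    acc = table[0][seq_idx[: n - m + 1]]
    for j in range(1, m):
        acc &= table[j][seq_idx[j : n - m + 1 + j]]
    return acc


def scan_motif(sequence: str, motif: MotifDef, both_strands: bool = True) -> MotifHits:
    """All (overlapping) IUPAC matches in ``sequence``.

    Plus-strand hits are start positions of the motif as written; with
    ``both_strands`` the reverse complement of the motif is also matched
    and reported with strand "-" at its plus-coordinate start position.
    A motif longer than the sequence yields count 0.
    """
    seq_idx = _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    hits: list[tuple[int, str]] = []
    fwd = _scan_strand(seq_idx, _allowed_table(motif))
    hits.extend((int(i), "+") for i in np.flatnonzero(fwd))
    if both_strands:
        rc = MotifDef(motif.name, reverse_complement(motif.iupac))
        rev = _scan_strand(seq_idx, _allowed_table(rc))
        hits.extend((int(i), "-") for i in np.flatnonzero(rev))
    hits.sort()
    return MotifHits(count=len(hits), positions=tuple(hits))


# -- gene models and extraction ------------------------------------------


class GeneModelError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Stranded exon structure of one gene (0-based half-open intervals)."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: gene needs >= 1 exon")
        ex = sorted(tuple(map(int, e)) for e in self.exons)
        for (s, e) in ex:
            if not 0 <= s < e:
                raise GeneModelError(f"{self.gene_id}: bad exon interval ({s}, {e})")
        for (a, b), (c, d) in zip(ex, ex[1:]):
            if c < b:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        )

    def upstream_interval(
        self, contig_length: int, length: int = DEFAULT_UPSTREAM_LENGTH
    ) -> tuple[int, int]:
        """Genomic interval of the region 5' of the first exon.

        Strand-aware ("first exon" is the 5'-most), truncated at contig
        bounds only — overlap with neighboring genes is not trimmed.
        """
        if self.strand == "+":
            return (max(0, self.start - length), self.start)
        return (self.end, min(contig_length, self.end + length))


def _fetch(genome, contig: str, start: int, end: int) -> str:
    """Slice a contig from a dict of strings or a pyfaidx.Fasta."""
    try:
        rec = genome[contig]
    except KeyError as exc:
        raise GeneModelError(f"contig {contig!r} absent from genome") from exc
    if end < start:
        raise GeneModelError(f"bad interval [{start}, {end})")
    return str(rec[start:end]).upper()


def _contig_length(genome, contig: str) -> int:
    try:
        return len(genome[contig])
    except KeyError as exc:
        raise GeneModelError(f"contig {contig!r} absent from genome") from exc


@dataclass(frozen=True)
class RegulatorySequence:
    """Extracted regulatory sequence of one gene.

    ``parts`` is an ordered list of (label, sequence): the upstream region
    first, then introns 5'->3' of the gene; minus-strand sequences are
    reverse-complemented so everything reads 5'->3' of the gene.
    ``intervals`` records the plus-strand genomic interval of each part
    for audit (BED export).
    """

    gene_id: str
    parts: tuple[tuple[str, str], ...]
    intervals: tuple[tuple[str, int, int], ...]

    def concatenated(self) -> str:
        return "".join(seq for _, seq in self.parts)

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.parts)


def extract_regulatory_region(
    gene: GeneModel, genome, upstream_length: int = DEFAULT_UPSTREAM_LENGTH
) -> RegulatorySequence:
    """4 kb upstream of the first exon plus all introns, gene orientation."""
    clen = _contig_length(genome, gene.contig)
    if gene.end > clen:
        raise GeneModelError(
            f"{gene.gene_id}: exon end {gene.end} beyond contig {gene.contig!r} ({clen} bp)"
        )
    up = gene.upstream_interval(clen, upstream_length)
    introns = list(gene.introns())
    ordered: list[tuple[str, tuple[int, int]]] = [("upstream", up)]
    if gene.strand == "+":
        ordered += [(f"intron_{i + 1}", iv) for i, iv in enumerate(introns)]
    else:
        ordered += [(f"intron_{i + 1}", iv) for i, iv in enumerate(reversed(introns))]
    parts = []
    intervals = []
    for label, (s, e) in ordered:
        seq = _fetch(genome, gene.contig, s, e)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        parts.append((label, seq))
        intervals.append((label, s, e))
    return RegulatorySequence(gene_id=gene.gene_id, parts=tuple(parts), intervals=tuple(intervals))


def build_hit_table(
    genes: Sequence[GeneModel],
    genome,
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    upstream_length: int = DEFAULT_UPSTREAM_LENGTH,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Per gene x motif match counts and presence over regulatory regions.

    Counts are summed across the upstream region and every intron; a motif
    never spans the junction between two parts. ``present`` is
    ``count >= 1`` — the binarized value the enrichment test consumes.
    """
    records = []
    tables = {m.name: (_allowed_table(m), _allowed_table(MotifDef(m.name, reverse_complement(m.iupac)))) for m in motifs}
    for gene in genes:
        region = extract_regulatory_region(gene, genome, upstream_length)
        seq_idxs = [
            _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            for _, seq in region.parts
        ]
        for m in motifs:
            fwd_t, rev_t = tables[m.name]
            count = 0
            for si in seq_idxs:
                count += int(_scan_strand(si, fwd_t).sum())
                if both_strands:
                    count += int(_scan_strand(si, rev_t).sum())
            records.append((gene.gene_id, m.name, count, count >= 1))
    return pd.DataFrame(records, columns=["gene_id", "motif", "count", "present"])


def presence_matrix(hit_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy hit table to genes x motifs booleans."""
    return hit_table.pivot(index="gene_id", columns="motif", values="present").fillna(False)
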