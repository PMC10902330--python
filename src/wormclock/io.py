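"""Readers and writers for the pipeline's on-disk formats.

Expression and metadata travel as TSV, genomes as 60-column FASTA, gene
models as GFF3 (1-based inclusive coordinates, ``gene``/``mRNA``/``exon``
features with ``ID=``/``Parent=`` attributes), regulatory intervals as BED
(0-based half-open), planted truth as JSON. Writers are deterministic:
stable row order and floats at 6 significant digits, with optional header
comments carrying the config hash and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .matrix import ExpressionMatrix, MatrixValidationError
from .regions import GeneModel, GeneModelError, MotifDef, RegulatorySequence
from .simulate import SimulationDesign, SyntheticTruth

FLOAT_FORMAT = "%.6g"


def _write_tsv(df: pd.DataFrame, path, index: bool, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)


# -- expression ----------------------------------------------------------


def write_expression(matrix: ExpressionMatrix, matrix_path, metadata_path,
                     header_comment: str | None = None) -> None:
    values = matrix.values.copy()
    values.index.name = "gene_id"
    _write_tsv(values, matrix_path, index=True, header_comment=header_comment)
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    _write_tsv(meta, metadata_path, index=True, header_comment=header_comment)


def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read and validate an expression TSV + sample-metadata TSV pair.

    Errors name the offending genes/samples: duplicate gene ids, samples
    missing from either file, and non-numeric or missing cells are all
    rejected.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]
    ].tolist()
    if non_numeric:
        raise MatrixValidationError(
            f"non-numeric expression values in samples: {non_numeric}"
        )
    try:
        return ExpressionMatrix(values, meta)
    except MatrixValidationError:
        raise


def write_rhythm_table(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_tsv(table, path, index=True, header_comment=header_comment)


def read_rhythm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


# -- genome / annotation -------------------------------------------------


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="") for contig, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(genes: Sequence[GeneModel], path, source: str = "wormclock") -> None:
    """Emit gene/mRNA/exon features, converting to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = g.start + 1, g.end
            fh.write(
                f"{g.contig}\t{source}\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\t{source}\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.e{i};Parent={mrna_id}\n"
                )


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_annotation(gff3_path, fasta_path) -> tuple[list[GeneModel], Fasta]:
    """Load gene models (GFF3) and an indexed genome handle (FASTA).

    Exons of all transcripts of a gene are merged into non-overlapping
    intervals; GFF3's 1-based inclusive coordinates become 0-based
    half-open. Every gene's contig must exist in the FASTA and its span
    must fit on the contig.
    """
    genome = Fasta(str(fasta_path))
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(g.start - 1, g.end)]
        if g.strand not in "+-":
            raise GeneModelError(f"{g.id}: unknown strand symbol {g.strand!r}")
        model = GeneModel(g.id, g.seqid, g.strand, _merge_intervals(exons))
        if model.contig not in genome:
            raise GeneModelError(f"{model.gene_id}: contig {model.contig!r} absent from FASTA")
        if model.end > len(genome[model.contig]):
            raise GeneModelError(
                f"{model.gene_id}: exon end {model.end} beyond contig "
                f"{model.contig!r} ({len(genome[model.contig])} bp)"
            )
        genes.append(model)
    return genes, genome


def write_regions_bed(
    regions: Iterable[RegulatorySequence], gene_contigs: Mapping[str, str], path
) -> None:
    """Audit BED (0-based half-open) of every extracted regulatory part.

    ``gene_contigs`` maps gene id -> contig name.
    """
    with open(path, "w") as fh:
        for region in regions:
            contig = gene_contigs[region.gene_id]
            for (label, s, e) in region.intervals:
                fh.write(f"{contig}\t{s}\t{e}\t{region.gene_id}:{label}\n")


# -- motifs / truth ------------------------------------------------------


def write_motifs(motifs: Sequence[MotifDef], path) -> None:
    pd.DataFrame([(m.name, m.iupac) for m in motifs], columns=["name", "iupac"]).to_csv(
        path, sep="\t", index=False
    )


def read_motifs(path) -> list[MotifDef]:
    df = pd.read_csv(path, sep="\t")
    return [MotifDef(str(r["name"]), str(r["iupac"])) for _, r in df.iterrows()]


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "genes": json.loads(truth.genes.reset_index().to_json(orient="records")),
        "design": None
        if truth.design is None
        else {
            "timepoints": list(truth.design.timepoints),
            "replicates_per_timepoint": truth.design.replicates_per_timepoint,
            "conditions": list(truth.design.conditions),
            "log2_baseline_mean": truth.design.log2_baseline_mean,
            "log2_baseline_sd": truth.design.log2_baseline_sd,
            "noise_sd": truth.design.noise_sd,
            "replicate_batch_sd": truth.design.replicate_batch_sd,
            "seed": truth.design.seed,
        },
        "condition_amplitude": None
        if truth.condition_amplitude is None
        else json.loads(truth.condition_amplitude.reset_index().to_json(orient="records")),
        "motif_placements": None
        if truth.motif_placements is None
        else json.loads(truth.motif_placements.to_json(orient="records")),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    genes = pd.DataFrame(payload["genes"]).set_index("gene_id")
    design = None
    if payload.get("design"):
        d = payload["design"]
        design = SimulationDesign(
            timepoints=tuple(d["timepoints"]),
            replicates_per_timepoint=d["replicates_per_timepoint"],
            conditions=tuple(d["conditions"]),
            log2_baseline_mean=d["log2_baseline_mean"],
            log2_baseline_sd=d["log2_baseline_sd"],
            noise_sd=d["noise_sd"],
            replicate_batch_sd=d.get("replicate_batch_sd", 0.0),
            seed=d["seed"],
        )
    cond_amp = None
    if payload.get("condition_amplitude") is not None:
        cond_amp = pd.DataFrame(payload["condition_amplitude"]).set_index("gene_id")
    placements = None
    if payload.get("motif_placements") is not None:
        placements = pd.DataFrame(
            payload["motif_placements"],
            columns=["gene_id", "motif", "contig", "start", "strand"],
        )
    return SyntheticTruth(
        genes=genes, design=design, condition_amplitude=cond_amp, motif_placements=placements
    )
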