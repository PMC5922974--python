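"""Readers and writers for FASTA, FASTQ, GFF3 and the pipeline TSV tables.

All TSV writers emit a fixed column order; readers validate required
columns and reject tables that do not carry them.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .models import (
    BarSeqReadModel,
    CountMatrix,
    ExperimentDesign,
    GeneModel,
    GFFParseError,
    PoolEntry,
    PoolIntegrityError,
    TDNAReadModel,
)

logger = logging.getLogger(__name__)

POOL_COLUMNS = (
    "barcode",
    "scaffold",
    "position",
    "strand",
    "n_genomic_reads",
    "n_pastend_reads",
    "status",
)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a Phred+33 FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3


@dataclass(frozen=True)
class GffDialect:
    """Which GFF3 feature types and attributes carry the gene structure."""

    gene_types: tuple[str, ...] = ("gene",)
    transcript_types: tuple[str, ...] = ("mRNA", "transcript")
    exon_types: tuple[str, ...] = ("exon",)
    cds_types: tuple[str, ...] = ("CDS",)
    utr5_types: tuple[str, ...] = ("five_prime_UTR",)
    utr3_types: tuple[str, ...] = ("three_prime_UTR",)
    id_attribute: str = "ID"


def load_gene_models(
    gff3_path: str | Path, dialect: GffDialect | None = None
) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels.

    GFF 1-based inclusive coordinates are converted to 0-based
    half-open. When UTR features are absent they are inferred as
    exon minus CDS. A gene with no CDS is retained with its CDS span
    set to the transcript span (with a warning).
    """
    dialect = dialect or GffDialect()
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GFFParseError(f"cannot parse {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.all_features(featuretype=dialect.gene_types):
        gene_id = gene.attributes.get(dialect.id_attribute, [gene.id])[0]
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype=dialect.exon_types)
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype=dialect.cds_types)
        ]
        tx_start, tx_end = gene.start - 1, gene.end
        if not exons:
            exons = [(tx_start, tx_end)]
        exons = _merge_intervals(exons)
        if cds:
            cds_start = min(a for a, _ in cds)
            cds_end = max(b for _, b in cds)
        else:
            logger.warning("gene %s has no CDS; using transcript span", gene_id)
            cds_start, cds_end = tx_start, tx_end
        utr5 = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype=dialect.utr5_types)
        ]
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype=dialect.utr3_types)
        ]
        if not utr5 and not utr3:
            utr5, utr3 = _infer_utrs(exons, cds_start, cds_end, gene.strand)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=gene.seqid,
                strand=gene.strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _infer_utrs(
    exons: list[tuple[int, int]], cds_start: int, cds_end: int, strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """UTRs as exon minus CDS span, split by side and reflected by strand."""
    left, right = [], []
    for a, b in exons:
        if a < cds_start:
            left.append((a, min(b, cds_start)))
        if b > cds_end:
            right.append((max(a, cds_end), b))
    if strand == "+":
        return left, right
    return right, left


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "tdnaseq") -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.scaffold}\t{source}"
            out.write(
                f"{base}\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.mRNA"
            out.write(
                f"{base}\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                out.write(
                    f"{base}\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                )
            for a, b in g.exons:
                ca, cb = max(a, g.cds_start), min(b, g.cds_end)
                if ca < cb:
                    out.write(
                        f"{base}\tCDS\t{ca + 1}\t{cb}\t.\t{g.strand}\t0\t"
                        f"Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# Pool / counts / design TSV


def write_pool(entries: Iterable[PoolEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "barcode": e.barcode,
                "scaffold": e.scaffold,
                "position": e.position,
                "strand": e.strand,
                "n_genomic_reads": e.n_genomic_reads,
                "n_pastend_reads": e.n_pastend_reads,
                "status": e.status,
            }
            for e in entries
        ],
        columns=list(POOL_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_pool(path: str | Path) -> list[PoolEntry]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "barcode": str,
            "scaffold": str,
            "position": int,
            "strand": str,
            "n_genomic_reads": int,
            "n_pastend_reads": int,
            "status": str,
        },
    )
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise PoolIntegrityError(f"pool table missing columns: {sorted(missing)}")
    kept = df[df["status"] == "kept"]["barcode"]
    dupes = kept[kept.duplicated()]
    if len(dupes):
        raise PoolIntegrityError(
            f"duplicate kept barcodes in pool: {sorted(set(dupes))[:5]}"
        )
    return [
        PoolEntry(
            barcode=row.barcode,
            scaffold=row.scaffold,
            position=int(row.position),
            strand=row.strand,
            n_genomic_reads=int(row.n_genomic_reads),
            n_pastend_reads=int(row.n_pastend_reads),
            status=row.status,
        )
        for row in df.itertuples()
    ]


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Counts as TSV; per-sample unknown/total tallies in '#' header lines."""
    with open(path, "w") as out:
        samples = matrix.samples
        out.write("#unknown_reads\t" + "\t".join(str(matrix.unknown_reads[s]) for s in samples) + "\n")
        out.write("#total_reads\t" + "\t".join(str(matrix.total_reads[s]) for s in samples) + "\n")
        out.write("barcode\t" + "\t".join(samples) + "\n")
        for bc, row in matrix.counts.iterrows():
            out.write(bc + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_counts(path: str | Path) -> CountMatrix:
    meta: dict[str, list[int]] = {}
    with open(path) as handle:
        header_lines = []
        for line in handle:
            if line.startswith("#"):
                key, *values = line[1:].rstrip("\n").split("\t")
                meta[key] = [int(v) for v in values]
            else:
                header_lines.append(line)
                break
        rest = handle.read()
    from io import StringIO

    df = pd.read_csv(StringIO("".join(header_lines) + rest), sep="\t", index_col="barcode")
    df.index.name = None
    unknown = pd.Series(meta.get("unknown_reads", [0] * df.shape[1]), index=df.columns)
    total = pd.Series(
        meta.get("total_reads"), index=df.columns
    ) if "total_reads" in meta else None
    return CountMatrix(df, unknown, total)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.table.loc[:, list(ExperimentDesign.REQUIRED_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )


def read_design(path: str | Path) -> ExperimentDesign:
    return ExperimentDesign(pd.read_csv(path, sep="\t", dtype=str).fillna(""))


# ---------------------------------------------------------------------------
# Read-model TOML files


def read_tdna_model(path: str | Path) -> TDNAReadModel:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return TDNAReadModel(**data)


def read_barseq_model(path: str | Path) -> BarSeqReadModel:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return BarSeqReadModel(**data)
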