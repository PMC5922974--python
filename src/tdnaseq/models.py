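"""Core domain types for barcoded T-DNA insertion analysis.

Coordinate convention: all intervals are 0-based half-open. GFF3 input
(1-based inclusive) is converted at the I/O boundary. An insertion
"position" is the genomic coordinate of the first genomic base at the
T-DNA junction on the read's mapped strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

DNA_ALPHABET = set("ACGTN")

#: statuses a barcode can carry in the mutant-pool table
POOL_STATUSES = (
    "kept",
    "off_by_one",
    "off_by_two",
    "past_end_head_to_tail",
    "past_end_head_to_head",
    "past_end_run_on",
    "ambiguous",
    "multilocus",
)


class PoolIntegrityError(ValueError):
    """Raised when a mutant-pool table violates its invariants."""


class GFFParseError(ValueError):
    """Raised when a GFF3 file cannot be interpreted."""


def _check_dna(name: str, seq: str, allow_empty: bool = False) -> None:
    if not seq and not allow_empty:
        raise ValueError(f"{name} must be a non-empty DNA sequence")
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class TDNAReadModel:
    """Description of the T-DNA construct as seen in a TnSeq read.

    A TnSeq read is expected to look like::

        [junk] flank_pre BARCODE flank_post ... tdna_end[:-j] GENOMIC...

    where ``j`` (0..border_trim) bases of the T-DNA border are missing
    because the border length retained in the final insertion is
    variable. Matching therefore requires only ``tdna_end`` minus its
    last ``border_trim`` bases and treats the remainder as optional.

    ``tdna_left_border``, ``tdna_right_border`` and ``vector_backbone``
    are the references used to recognise past-end reads (concatemer
    junctions and unprocessed vector respectively).
    """

    flank_pre: str
    flank_post: str
    tdna_end: str
    vector_backbone: str = ""
    tdna_left_border: str = ""
    tdna_right_border: str = ""
    barcode_len_min: int = 17
    barcode_len_max: int = 23
    border_trim: int = 10

    def __post_init__(self) -> None:
        _check_dna("flank_pre", self.flank_pre)
        _check_dna("flank_post", self.flank_post)
        _check_dna("tdna_end", self.tdna_end)
        for name in ("vector_backbone", "tdna_left_border", "tdna_right_border"):
            _check_dna(name, getattr(self, name), allow_empty=True)
        if not (0 < self.barcode_len_min <= self.barcode_len_max):
            raise ValueError("require 0 < barcode_len_min <= barcode_len_max")
        if self.border_trim < 0:
            raise ValueError("border_trim must be >= 0")
        if len(self.tdna_end) <= self.border_trim:
            raise ValueError(
                "tdna_end must be longer than border_trim so a required "
                "anchor remains after ignoring the variable border end"
            )

    @property
    def tdna_end_required(self) -> str:
        """The part of the T-DNA end that must match in every read."""
        return self.tdna_end[: len(self.tdna_end) - self.border_trim]

    @property
    def tdna_end_optional(self) -> str:
        """The final ``border_trim`` bases, variably retained."""
        return self.tdna_end[len(self.tdna_end) - self.border_trim :]

    def pastend_references(self) -> dict[str, str]:
        """Named references diagnostic of past-end reads."""
        refs = {}
        if self.tdna_left_border:
            refs["left_border"] = self.tdna_left_border
        if self.tdna_right_border:
            refs["right_border"] = self.tdna_right_border
        if self.vector_backbone:
            refs["vector"] = self.vector_backbone
        return refs


@dataclass(frozen=True)
class BarSeqReadModel:
    """Structure of a BarSeq amplicon read.

    Reads start with ``offset_min``..``offset_max`` random bases (added
    for nucleotide balance on low-diversity lanes), then the fixed
    priming site ``pre_seq``, the barcode, and ``post_seq``.
    """

    pre_seq: str
    post_seq: str
    offset_min: int = 2
    offset_max: int = 4
    barcode_len_min: int = 17
    barcode_len_max: int = 23

    def __post_init__(self) -> None:
        _check_dna("pre_seq", self.pre_seq)
        _check_dna("post_seq", self.post_seq)
        if not (0 <= self.offset_min <= self.offset_max):
            raise ValueError("require 0 <= offset_min <= offset_max")
        if not (0 < self.barcode_len_min <= self.barcode_len_max):
            raise ValueError("require 0 < barcode_len_min <= barcode_len_max")


@dataclass
class GeneModel:
    """One gene: transcript span, exon structure and CDS span.

    ``cds_start``/``cds_end`` run from start codon to stop codon with
    introns included in the span. UTR intervals are exon minus CDS,
    assigned to the 5'/3' side according to strand.
    """

    gene_id: str
    scaffold: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.gene_id}: CDS span must nest within transcript span"
            )
        self.exons = sorted(tuple(e) for e in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for a, b in self.utr5 + self.utr3:
            if not (self.tx_start <= a < b <= self.tx_end):
                raise ValueError(f"{self.gene_id}: UTR interval outside transcript")
            if a < self.cds_end and b > self.cds_start:
                raise ValueError(f"{self.gene_id}: UTR interval overlaps CDS span")

    @property
    def cds_span_kb(self) -> float:
        return (self.cds_end - self.cds_start) / 1000.0

    def contains(self, position: int) -> bool:
        return self.tx_start <= position < self.tx_end

    def feature_at(self, position: int) -> str:
        """Feature class for a position inside the transcript span.

        Exonic bases overlapping the CDS span are 'exon'; exonic bases
        outside it are UTR (side reflected by strand); everything else
        within the transcript is 'intron'.
        """
        if not self.contains(position):
            raise ValueError(f"position {position} outside {self.gene_id}")
        in_exon = any(a <= position < b for a, b in self.exons)
        if not in_exon:
            return "intron"
        if self.cds_start <= position < self.cds_end:
            return "exon"
        upstream_of_cds = position < self.cds_start
        if (upstream_of_cds and self.strand == "+") or (
            not upstream_of_cds and self.strand == "-"
        ):
            return "utr5"
        return "utr3"


@dataclass
class PoolEntry:
    """One barcode in (or filtered out of) the mutant pool."""

    barcode: str
    scaffold: str
    position: int
    strand: str
    n_genomic_reads: int
    n_pastend_reads: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in POOL_STATUSES:
            raise ValueError(f"unknown pool status {self.status!r}")
        if self.n_genomic_reads < 0 or self.n_pastend_reads < 0:
            raise ValueError("read counts must be >= 0")


class CountMatrix:
    """Barcode x sample integer counts with per-sample read accounting.

    ``unknown_reads`` tallies reads whose extracted barcode is not in
    the pool; ``total_reads`` is the number of reads processed for the
    sample, so ``column sum + unknown_reads <= total_reads`` (reads with
    no extractable barcode make up the difference).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        unknown_reads: pd.Series | None = None,
        total_reads: pd.Series | None = None,
    ) -> None:
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        samples = counts.columns
        zero = pd.Series(0, index=samples, dtype=np.int64)
        self.unknown_reads = (
            zero.copy() if unknown_reads is None else unknown_reads.reindex(samples).fillna(0).astype(np.int64)
        )
        if total_reads is None:
            total_reads = counts.sum(axis=0) + self.unknown_reads
        self.total_reads = total_reads.reindex(samples).fillna(0).astype(np.int64)
        accounted = counts.sum(axis=0) + self.unknown_reads
        if (accounted > self.total_reads).any():
            raise ValueError("column sum + unknown_reads exceeds total_reads")

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_counts(self, sample: str) -> pd.Series:
        return self.counts[sample]

    @staticmethod
    def merge(matrices: list["CountMatrix"]) -> "CountMatrix":
        """Column-wise merge of single/multi-sample matrices.

        Barcode sets are unioned (missing counts are 0); sample IDs must
        be distinct across inputs.
        """
        if not matrices:
            raise ValueError("nothing to merge")
        all_samples = [s for m in matrices for s in m.samples]
        if len(set(all_samples)) != len(all_samples):
            raise ValueError("duplicate sample IDs across matrices")
        counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0)
        unknown = pd.concat([m.unknown_reads for m in matrices])
        total = pd.concat([m.total_reads for m in matrices])
        return CountMatrix(counts, unknown, total)


class ExperimentDesign:
    """Sample sheet pairing condition samples with their Time-0 samples.

    Each row: sample_id, replicate_id, condition_label, role
    ('time0' or 'condition'), paired_time0_sample. Every condition
    sample must name exactly one time0 sample from the same replicate
    (the starter culture it was seeded from).
    """

    REQUIRED_COLUMNS = (
        "sample_id",
        "replicate_id",
        "condition_label",
        "role",
        "paired_time0_sample",
    )

    def __init__(self, table: pd.DataFrame) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        table = table.copy()
        bad_roles = set(table["role"]) - {"time0", "condition"}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        t0 = table[table["role"] == "time0"]
        t0_by_id = t0.set_index("sample_id")
        for _, row in table[table["role"] == "condition"].iterrows():
            ref = row["paired_time0_sample"]
            if ref not in t0_by_id.index:
                raise ValueError(
                    f"condition sample {row['sample_id']} pairs with unknown "
                    f"time0 sample {ref!r}"
                )
            if t0_by_id.loc[ref, "replicate_id"] != row["replicate_id"]:
                raise ValueError(
                    f"condition sample {row['sample_id']} pairs with a time0 "
                    f"sample from a different replicate"
                )
        self.table = table

    def conditions(self) -> list[str]:
        mask = self.table["role"] == "condition"
        return sorted(self.table.loc[mask, "condition_label"].unique())

    def pairs(self, condition_label: str | None = None) -> Iterator[tuple[str, str, str, str]]:
        """Yield (condition_sample, time0_sample, replicate_id, condition_label)."""
        rows = self.table[self.table["role"] == "condition"]
        if condition_label is not None:
            rows = rows[rows["condition_label"] == condition_label]
        for _, row in rows.iterrows():
            yield (
                row["sample_id"],
                row["paired_time0_sample"],
                row["replicate_id"],
                row["condition_label"],
            )

    def time0_samples(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "time0", "sample_id"])


@dataclass
class GeneFitnessRecord:
    """Per-gene, per-condition fitness summary."""

    gene_id: str
    condition_label: str
    F: float
    varF: float
    T: float
    n_barcodes: int
    n_strains_passing: int

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("emitted records need at least one barcode")
        if self.varF > 0 and np.isfinite(self.T):
            expected = self.F / np.sqrt(self.varF)
            if not np.isclose(self.T, expected, rtol=1e-6, atol=1e-9):
                raise ValueError("T must equal F / sqrt(varF)")
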