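"""Synthetic data generation: toy genomes with annotated genes, barcoded
insertion pools, TnSeq/BarSeq reads with injected artifact classes, and
growth-simulated BarSeq counts under known per-gene fitness effects.

Every generator takes (or derives) a numpy Generator so outputs are
fully deterministic under a seed, and every stage emits a truth table
sufficient to score the corresponding pipeline stage. Injected
artifacts mirror the pool filters' targets: off-by-one barcode
variants below 1/100 of their parent's abundance, past-end reads
matching T-DNA borders or vector, multilocus chimeras with a second
location carrying >= 20% of reads, near-identical neighbour barcodes
within 10 bases, and ambiguously mapping insertions inside a duplicated
genomic segment. Some injected cases sit just below each filter's
threshold so boundary behaviour is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .io import _infer_utrs
from .models import (
    BarSeqReadModel,
    CountMatrix,
    ExperimentDesign,
    GeneModel,
    TDNAReadModel,
)

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _construct_seqs() -> dict[str, str]:
    # synthetic construct sequences for the toy T-DNA (fixed stream so the
    # default model is a constant); the barcode flanks are the priming
    # sites of the barcoding oligo
    rng = np.random.default_rng(715)
    return {
        "tdna_end": random_dna(rng, 40),
        "left_border": random_dna(rng, 150),
        "right_border": random_dna(rng, 150),
        "vector": random_dna(rng, 400),
    }


_SEQS = _construct_seqs()

DEFAULT_TDNA_MODEL = TDNAReadModel(
    flank_pre="GATGTCCACGAGGTCTCT",
    flank_post="CGTACGCTGCAGGTCGAC",
    tdna_end=_SEQS["tdna_end"],
    vector_backbone=_SEQS["vector"],
    tdna_left_border=_SEQS["left_border"],
    tdna_right_border=_SEQS["right_border"],
)

DEFAULT_BARSEQ_MODEL = BarSeqReadModel(
    pre_seq="GATGTCCACGAGGTCTCT",
    post_seq="CGTACGCTGCAGGTCGAC",
)

#: barcode length distribution: mostly 20-mers, ~10% slightly off
BARCODE_LENGTHS = np.arange(17, 24)
BARCODE_LENGTH_PROBS = np.array([0.01, 0.02, 0.05, 0.84, 0.05, 0.02, 0.01])


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline substrate."""

    seed: int
    # genome / annotation
    genome_length: int = 300_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (900, 2400)
    n_exons_range: tuple[int, int] = (1, 3)
    intron_length_range: tuple[int, int] = (60, 140)
    utr_length_range: tuple[int, int] = (30, 150)
    intergenic_gap_range: tuple[int, int] = (150, 600)
    duplicate_segment_length: int = 400
    # insertion pool
    n_insertions: int = 2000
    essential_gene_fraction: float = 0.03
    cds_density_per_kb: float | None = None
    min_cds_per_kb: float | None = None
    feature_multipliers: dict = field(default_factory=dict)
    # TnSeq reads
    mean_reads_per_barcode: float = 10.0
    fragment_length_range: tuple[int, int] = (30, 60)
    substitution_rate: float = 0.005
    off_by_one_rate: float = 0.02
    past_end_rate_head_to_tail: float = 0.02
    past_end_rate_head_to_head: float = 0.005
    past_end_rate_run_on: float = 0.005
    multilocus_rate: float = 0.02
    off_by_two_rate: float = 0.02
    ambiguous_rate: float = 0.01
    boundary_cases: bool = True
    # growth / BarSeq
    generations: float = 7.0
    depth_per_strain: float = 50.0
    n_replicates: int = 3
    time0_dirichlet_alpha: float = 100.0
    growth_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        rates = [
            self.substitution_rate,
            self.off_by_one_rate,
            self.past_end_rate_head_to_tail,
            self.past_end_rate_head_to_head,
            self.past_end_rate_run_on,
            self.multilocus_rate,
            self.off_by_two_rate,
            self.ambiguous_rate,
            self.essential_gene_fraction,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GenomeTruth:
    genome: dict[str, str]
    genes: list[GeneModel]
    essential_gene_ids: set[str]
    duplicated_regions: list[tuple[str, int, int]]

    @property
    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "scaffold": g.scaffold,
                    "strand": g.strand,
                    "tx_start": g.tx_start,
                    "tx_end": g.tx_end,
                    "cds_start": g.cds_start,
                    "cds_end": g.cds_end,
                    "essential": g.gene_id in self.essential_gene_ids,
                }
                for g in self.genes
            ]
        )


# ---------------------------------------------------------------------------
# Genome and genes


def _make_gene(
    gene_id: str, scaffold: str, start: int, rng: np.random.Generator, cfg: SimConfig
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    utr_a = int(rng.integers(*cfg.utr_length_range))
    utr_b = int(rng.integers(*cfg.utr_length_range))
    n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
    total = int(rng.integers(*cfg.gene_length_range))
    intron_lens = [
        int(rng.integers(*cfg.intron_length_range)) for _ in range(n_exons - 1)
    ]
    coding_total = max(total - utr_a - utr_b - sum(intron_lens), 150 * n_exons)
    cuts = np.sort(rng.integers(1, coding_total, n_exons - 1)) if n_exons > 1 else []
    exon_core = np.diff(np.concatenate(([0], cuts, [coding_total])))
    exon_core = np.maximum(exon_core, 30)

    exons: list[tuple[int, int]] = []
    pos = start
    for i, core in enumerate(exon_core):
        length = int(core)
        if i == 0:
            length += utr_a
        if i == len(exon_core) - 1:
            length += utr_b
        exons.append((pos, pos + length))
        pos += length
        if i < len(intron_lens):
            pos += intron_lens[i]
    tx_start, tx_end = exons[0][0], exons[-1][1]
    cds_start = tx_start + utr_a
    cds_end = tx_end - utr_b
    utr5, utr3 = _infer_utrs(exons, cds_start, cds_end, strand)
    return GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exons,
        utr5=utr5,
        utr3=utr3,
    )


def make_genome_and_genes(cfg: SimConfig) -> GenomeTruth:
    """A random genome with non-overlapping genes on both strands.

    One intergenic segment is duplicated verbatim to another intergenic
    location so that reads from it map ambiguously (the substrate for
    the ambiguous-read filter). Essential genes are designated up front;
    the pool generator gives their CDS spans zero insertions.
    """
    rng = cfg.rng(stream=1)
    scaffold = "scaffold_1"
    seq = list(random_dna(rng, cfg.genome_length))

    genes: list[GeneModel] = []
    pos = int(rng.integers(*cfg.intergenic_gap_range)) + cfg.duplicate_segment_length
    for i in range(cfg.n_genes):
        gene = _make_gene(f"G{i + 1:04d}", scaffold, pos, rng, cfg)
        if gene.tx_end + cfg.duplicate_segment_length + 10 >= cfg.genome_length:
            raise ValueError(
                f"cannot pack {cfg.n_genes} genes into {cfg.genome_length} bases"
            )
        genes.append(gene)
        pos = gene.tx_end + int(rng.integers(*cfg.intergenic_gap_range))

    # duplicate an intergenic segment near the start into the tail gap
    dup_len = cfg.duplicate_segment_length
    dup_regions: list[tuple[str, int, int]] = []
    if dup_len > 0:
        src_start = 0
        dst_start = cfg.genome_length - dup_len
        if dst_start > genes[-1].tx_end:
            seq[dst_start : dst_start + dup_len] = seq[src_start : src_start + dup_len]
            dup_regions = [
                (scaffold, src_start, src_start + dup_len),
                (scaffold, dst_start, dst_start + dup_len),
            ]

    n_essential = int(round(cfg.essential_gene_fraction * cfg.n_genes))
    essential = set(
        rng.choice([g.gene_id for g in genes], size=n_essential, replace=False).tolist()
    )
    return GenomeTruth(
        genome={scaffold: "".join(seq)},
        genes=genes,
        essential_gene_ids=essential,
        duplicated_regions=dup_regions,
    )


# ---------------------------------------------------------------------------
# Insertion pool


def make_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct random barcodes, length 17-23 with mode 20."""
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n:
        length = int(rng.choice(BARCODE_LENGTHS, p=BARCODE_LENGTH_PROBS))
        bc = random_dna(rng, length)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    return barcodes


def _forbidden_mask(truth: GenomeTruth, margin: int, cfg: SimConfig) -> np.ndarray:
    """Bases where clean insertions must not land.

    Excludes essential-gene CDS spans (by construction), scaffold edges
    (so full fragments exist) and duplicated segments (reserved for
    ambiguous artifacts).
    """
    scaffold = next(iter(truth.genome))
    n = len(truth.genome[scaffold])
    bad = np.zeros(n, dtype=bool)
    bad[: margin + 1] = True
    bad[n - margin :] = True
    for g in truth.genes:
        if g.gene_id in truth.essential_gene_ids:
            bad[g.cds_start : g.cds_end] = True
    for _, a, b in truth.duplicated_regions:
        bad[max(0, a - margin) : min(n, b + margin)] = True
    return bad


def make_true_pool(cfg: SimConfig, truth: GenomeTruth) -> pd.DataFrame:
    """Barcoded insertions at known sites (the truth pool).

    Positions are uniform over allowed bases unless per-feature
    multipliers or a per-gene CDS density are configured; essential
    genes receive zero CDS insertions by construction. Returns one row
    per insertion: barcode, scaffold, position, strand, gene_id (the
    CDS-containing gene, if any), insertion_frac (relative position
    within that CDS span) and expected_status='kept'.
    """
    rng = cfg.rng(stream=2)
    scaffold = next(iter(truth.genome))
    margin = cfg.fragment_length_range[1] + 5
    bad = _forbidden_mask(truth, margin, cfg)

    positions: list[int] = []
    if cfg.cds_density_per_kb is not None:
        for g in truth.genes:
            if g.gene_id in truth.essential_gene_ids:
                continue
            kb = (g.cds_end - g.cds_start) / 1000.0
            n_g = int(rng.poisson(cfg.cds_density_per_kb * kb))
            if cfg.min_cds_per_kb is not None:
                n_g = max(n_g, math.ceil(cfg.min_cds_per_kb * kb))
            cand = np.arange(g.cds_start, g.cds_end)
            cand = cand[~bad[cand]]
            n_g = min(n_g, len(cand))
            positions.extend(rng.choice(cand, size=n_g, replace=False).tolist())
    else:
        weights = np.ones(len(truth.genome[scaffold]))
        if cfg.feature_multipliers:
            from .annotate import PARTITION_CLASSES, build_feature_partition

            part = build_feature_partition(
                truth.genes, {scaffold: len(truth.genome[scaffold])}
            )[scaffold]
            for name, mult in cfg.feature_multipliers.items():
                weights[part == PARTITION_CLASSES.index(name)] = mult
        weights[bad] = 0.0
        # weighted sampling without replacement via Gumbel top-k
        with np.errstate(divide="ignore"):
            keys = np.log(weights) + rng.gumbel(size=len(weights))
        if cfg.n_insertions > np.count_nonzero(weights):
            raise ValueError("more insertions requested than allowed positions")
        top = np.argpartition(-keys, cfg.n_insertions)[: cfg.n_insertions]
        positions = sorted(int(p) for p in top)

    strands = np.where(rng.random(len(positions)) < 0.5, "+", "-")
    barcodes = make_barcodes(rng, len(positions))

    cds_starts = np.array([g.cds_start for g in truth.genes])
    cds_ends = np.array([g.cds_end for g in truth.genes])
    gene_ids = [g.gene_id for g in truth.genes]
    rows = []
    for bc, p, s in zip(barcodes, positions, strands):
        gene_id, frac = None, np.nan
        j = int(np.searchsorted(cds_starts, p, side="right")) - 1
        if j >= 0 and p < cds_ends[j]:
            gene_id = gene_ids[j]
            frac = (p - cds_starts[j]) / (cds_ends[j] - cds_starts[j])
        rows.append(
            {
                "barcode": bc,
                "scaffold": scaffold,
                "position": int(p),
                "strand": s,
                "gene_id": gene_id,
                "insertion_frac": frac,
                "expected_status": "kept",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TnSeq reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _genomic_fragment(
    genome: dict[str, str], scaffold: str, position: int, strand: str, length: int
) -> str:
    seq = genome[scaffold]
    if strand == "+":
        return seq[position : position + length]
    return revcomp(seq[max(0, position - length + 1) : position + 1])


def _mutate_barcode(bc: str, rng: np.random.Generator, n_edits: int = 1) -> str:
    out = bc
    for _ in range(n_edits):
        kind = rng.integers(0, 3)
        i = int(rng.integers(0, len(out)))
        if kind == 0 or len(out) <= 17:  # substitution
            choices = [b for b in "ACGT" if b != out[i]]
            out = out[:i] + choices[rng.integers(0, 3)] + out[i + 1 :]
        elif kind == 1 and len(out) < 23:  # insertion
            out = out[:i] + "ACGT"[rng.integers(0, 4)] + out[i:]
        else:  # deletion
            out = out[:i] + out[i + 1 :]
    return out


@dataclass
class TnSeqTruth:
    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # barcode, expected_status, scaffold, position, strand


def make_tnseq_reads(
    pool: pd.DataFrame,
    truth: GenomeTruth,
    cfg: SimConfig,
    model: TDNAReadModel = DEFAULT_TDNA_MODEL,
) -> TnSeqTruth:
    """TnSeq reads for the truth pool plus injected artifact barcodes.

    Each insertion retains a fixed, random number of the optional
    T-DNA border bases (the border length in the final insertion is
    variable); reads carry per-base substitution errors. Truth rows
    record the filter status each barcode should receive.
    """
    rng = cfg.rng(stream=3)
    genome = truth.genome
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    counter = 0

    def emit(bc: str, fragment: str, retained: str) -> None:
        nonlocal counter
        counter += 1
        seq = (
            model.flank_pre
            + bc
            + model.flank_post
            + model.tdna_end_required
            + retained
            + fragment
        )
        reads.append((f"r{counter:07d}", _apply_errors(seq, cfg.substitution_rate, rng)))

    def emit_genomic(bc: str, scaffold: str, pos: int, strand: str, n: int, retained: str):
        for _ in range(n):
            length = int(rng.integers(*cfg.fragment_length_range))
            emit(bc, _genomic_fragment(genome, scaffold, pos, strand, length), retained)

    def retained_border() -> str:
        keep = int(rng.integers(0, model.border_trim + 1))
        return model.tdna_end_optional[:keep]

    n_clean = len(pool)
    n_reads = np.maximum(1, rng.poisson(cfg.mean_reads_per_barcode, n_clean))

    # choose off-by-one parents up front so their abundance can be boosted
    n_ob1 = int(round(cfg.off_by_one_rate * n_clean))
    parent_idx = rng.choice(n_clean, size=min(n_ob1 + 2, n_clean), replace=False)
    ob1_parents = parent_idx[:n_ob1]
    boundary_parents = parent_idx[n_ob1:] if cfg.boundary_cases else parent_idx[:0]
    n_reads[ob1_parents] = rng.integers(240, 320, size=len(ob1_parents))
    n_reads[boundary_parents] = 160

    retained_by_row = []
    for i, row in enumerate(pool.itertuples()):
        ret = retained_border()
        retained_by_row.append(ret)
        emit_genomic(row.barcode, row.scaffold, row.position, row.strand, int(n_reads[i]), ret)
        truth_rows.append(
            {
                "barcode": row.barcode,
                "expected_status": "kept",
                "scaffold": row.scaffold,
                "position": row.position,
                "strand": row.strand,
                "artifact": "",
            }
        )

    scaffold = next(iter(genome))
    used = set(pool["barcode"])

    def fresh_variant(parent_bc: str, n_edits: int) -> str:
        for _ in range(50):
            cand = _mutate_barcode(parent_bc, rng, n_edits)
            if cand not in used:
                used.add(cand)
                return cand
        raise RuntimeError("could not generate a fresh barcode variant")

    # off-by-one: distance-1 variants at < 1/100 of the parent's reads
    for i in ob1_parents:
        parent = pool.iloc[i]
        child = fresh_variant(parent.barcode, 1)
        emit_genomic(child, parent.scaffold, parent.position, parent.strand, 2, retained_by_row[i])
        truth_rows.append(
            {
                "barcode": child,
                "expected_status": "off_by_one",
                "scaffold": parent.scaffold,
                "position": parent.position,
                "strand": parent.strand,
                "artifact": "off_by_one",
            }
        )
    # boundary: ratio 80x < 100x escapes the off-by-one rule, but the same
    # pair then satisfies the off-by-two rule (same location, edit distance
    # 1 < 5, parent more abundant), so the cascade label is off_by_two
    for i in boundary_parents:
        parent = pool.iloc[i]
        child = fresh_variant(parent.barcode, 1)
        emit_genomic(child, parent.scaffold, parent.position, parent.strand, 2, retained_by_row[i])
        truth_rows.append(
            {
                "barcode": child,
                "expected_status": "off_by_two",
                "scaffold": parent.scaffold,
                "position": parent.position,
                "strand": parent.strand,
                "artifact": "off_by_one_below_threshold",
            }
        )

    # past-end concatemer / run-on barcodes
    pastend_specs = [
        ("past_end_head_to_tail", model.tdna_left_border, cfg.past_end_rate_head_to_tail),
        ("past_end_head_to_head", model.tdna_right_border, cfg.past_end_rate_head_to_head),
        ("past_end_run_on", model.vector_backbone, cfg.past_end_rate_run_on),
    ]
    free_positions = np.flatnonzero(~_forbidden_mask(truth, cfg.fragment_length_range[1] + 5, cfg))

    def random_clean_site() -> int:
        return int(rng.choice(free_positions))

    for status, ref, rate in pastend_specs:
        for _ in range(int(round(rate * n_clean))):
            bc = fresh_variant(random_dna(rng, 20), 0)
            site = random_clean_site()
            ret = retained_border()
            emit_genomic(bc, scaffold, site, "+", 1, ret)
            n_pe = 10 + int(rng.poisson(4))
            for _ in range(n_pe):
                length = int(rng.integers(*cfg.fragment_length_range))
                start = int(rng.integers(0, max(1, len(ref) - length)))
                emit(bc, ref[start : start + length], ret)
            truth_rows.append(
                {
                    "barcode": bc,
                    "expected_status": status,
                    "scaffold": scaffold,
                    "position": site,
                    "strand": "+",
                    "artifact": status,
                }
            )
    if cfg.boundary_cases:
        # exactly 7x past-end vs genomic: not flagged ("more than seven")
        bc = fresh_variant(random_dna(rng, 20), 0)
        site = random_clean_site()
        ret = retained_border()
        emit_genomic(bc, scaffold, site, "+", 2, ret)
        for _ in range(14):
            length = int(rng.integers(*cfg.fragment_length_range))
            start = int(rng.integers(0, len(model.tdna_left_border) - length))
            emit(bc, model.tdna_left_border[start : start + length], ret)
        truth_rows.append(
            {
                "barcode": bc,
                "expected_status": "kept",
                "scaffold": scaffold,
                "position": site,
                "strand": "+",
                "artifact": "past_end_at_threshold",
            }
        )

    # multilocus chimeras: a second location with >= 20% of genomic reads
    for _ in range(int(round(cfg.multilocus_rate * n_clean))):
        bc = fresh_variant(random_dna(rng, 20), 0)
        p1, p2 = random_clean_site(), random_clean_site()
        total = 10 + int(rng.poisson(5))
        frac = rng.uniform(0.25, 0.45)
        n2 = max(2, int(round(frac * total)))
        ret = retained_border()
        emit_genomic(bc, scaffold, p1, "+", total - n2, ret)
        emit_genomic(bc, scaffold, p2, "+", n2, ret)
        truth_rows.append(
            {
                "barcode": bc,
                "expected_status": "multilocus",
                "scaffold": scaffold,
                "position": p1,
                "strand": "+",
                "artifact": "multilocus",
            }
        )
    if cfg.boundary_cases:
        # 10% at a second location: kept (< 20%)
        bc = fresh_variant(random_dna(rng, 20), 0)
        p1, p2 = random_clean_site(), random_clean_site()
        ret = retained_border()
        emit_genomic(bc, scaffold, p1, "+", 18, ret)
        emit_genomic(bc, scaffold, p2, "+", 2, ret)
        truth_rows.append(
            {
                "barcode": bc,
                "expected_status": "kept",
                "scaffold": scaffold,
                "position": p1,
                "strand": "+",
                "artifact": "multilocus_below_threshold",
            }
        )

    # off-by-two: similar barcode within 10 bases of a more abundant one
    candidates = [i for i in range(n_clean) if i not in set(parent_idx)]
    n_ob2 = int(round(cfg.off_by_two_rate * n_clean))
    ob2_parents = rng.choice(candidates, size=n_ob2, replace=False)
    for i in ob2_parents:
        parent = pool.iloc[i]
        child = fresh_variant(parent.barcode, int(rng.integers(2, 5)))
        delta = int(rng.integers(1, 9)) * (1 if rng.random() < 0.5 else -1)
        child_pos = int(np.clip(parent.position + delta, 70, len(genome[scaffold]) - 70))
        n_child = max(1, int(n_reads[i]) // 3)
        emit_genomic(child, parent.scaffold, child_pos, parent.strand, n_child, retained_border())
        truth_rows.append(
            {
                "barcode": child,
                "expected_status": "off_by_two",
                "scaffold": parent.scaffold,
                "position": child_pos,
                "strand": parent.strand,
                "artifact": "off_by_two",
            }
        )

    # ambiguous: insertions inside the duplicated segment
    if truth.duplicated_regions:
        _, a, b = truth.duplicated_regions[0]
        max_frag = cfg.fragment_length_range[1]
        for _ in range(int(round(cfg.ambiguous_rate * n_clean))):
            bc = fresh_variant(random_dna(rng, 20), 0)
            pos = int(rng.integers(a + 5, b - max_frag - 5))
            emit_genomic(bc, scaffold, pos, "+", max(1, int(rng.poisson(cfg.mean_reads_per_barcode))), retained_border())
            truth_rows.append(
                {
                    "barcode": bc,
                    "expected_status": "ambiguous",
                    "scaffold": scaffold,
                    "position": pos,
                    "strand": "+",
                    "artifact": "ambiguous",
                }
            )

    return TnSeqTruth(reads=reads, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# BarSeq reads and growth-simulated counts


def make_barseq_reads(
    barcode_counts: dict[str, int],
    cfg: SimConfig,
    model: BarSeqReadModel = DEFAULT_BARSEQ_MODEL,
    read_length: int = 75,
) -> list[tuple[str, str]]:
    """BarSeq reads: random leading bases, priming sites, barcode, filler."""
    rng = cfg.rng(stream=4)
    reads = []
    i = 0
    for bc, n in barcode_counts.items():
        for _ in range(n):
            i += 1
            offset = int(rng.integers(model.offset_min, model.offset_max + 1))
            seq = random_dna(rng, offset) + model.pre_seq + bc + model.post_seq
            if len(seq) < read_length:
                seq += random_dna(rng, read_length - len(seq))
            reads.append((f"b{i:07d}", _apply_errors(seq, cfg.substitution_rate, rng)))
    order = rng.permutation(len(reads))
    return [reads[j] for j in order]


def simulate_barseq_counts(
    strain_table: pd.DataFrame,
    condition_effects: dict[str, dict[str, float]],
    cfg: SimConfig,
) -> tuple[CountMatrix, ExperimentDesign]:
    """Growth-simulated BarSeq counts under known per-gene fitness effects.

    ``strain_table``: one row per barcode with a ``gene_id`` column
    (NaN/None = intergenic, effect 0). ``condition_effects`` maps each
    condition label to per-gene true fitness: the log2 change in
    relative abundance over the experiment (growth is ``generations``
    doublings at ``effect / generations`` per generation, so final
    abundance is initial x 2^effect before renormalisation).

    Per replicate, Time-0 abundances are Dirichlet-perturbed around
    uniform and counts are multinomial at ``depth_per_strain`` mean
    depth. A small per-strain lognormal growth noise is applied.
    """
    rng = cfg.rng(stream=5)
    barcodes = strain_table["barcode"].tolist()
    genes = strain_table["gene_id"].tolist()
    n = len(barcodes)
    depth = int(round(cfg.depth_per_strain * n))

    samples: dict[str, np.ndarray] = {}
    design_rows = []
    for r in range(1, cfg.n_replicates + 1):
        rep = f"rep{r}"
        t0_name = f"T0_{rep}"
        alpha = np.full(n, cfg.time0_dirichlet_alpha)
        p0 = rng.dirichlet(alpha)
        samples[t0_name] = rng.multinomial(depth, p0)
        design_rows.append(
            {
                "sample_id": t0_name,
                "replicate_id": rep,
                "condition_label": "Time0",
                "role": "time0",
                "paired_time0_sample": "",
            }
        )
        for label, effects in condition_effects.items():
            eff = np.array(
                [effects.get(g, 0.0) if g is not None and g == g else 0.0 for g in genes]
            )
            noise = rng.normal(0.0, cfg.growth_noise_sd, n)
            p = p0 * np.exp2(eff + noise)
            p /= p.sum()
            name = f"{label}_{rep}"
            samples[name] = rng.multinomial(depth, p)
            design_rows.append(
                {
                    "sample_id": name,
                    "replicate_id": rep,
                    "condition_label": label,
                    "role": "condition",
                    "paired_time0_sample": t0_name,
                }
            )

    counts = pd.DataFrame(samples, index=barcodes)
    design = ExperimentDesign(pd.DataFrame(design_rows))
    return CountMatrix(counts), design


def make_strain_table(
    n_genes: int,
    barcodes_per_gene: int,
    rng: np.random.Generator,
    n_intergenic: int = 0,
) -> pd.DataFrame:
    """Barcode -> gene assignment for count-level simulations."""
    n_total = n_genes * barcodes_per_gene + n_intergenic
    barcodes = make_barcodes(rng, n_total)
    rows = []
    i = 0
    for g in range(1, n_genes + 1):
        for _ in range(barcodes_per_gene):
            rows.append(
                {
                    "barcode": barcodes[i],
                    "gene_id": f"G{g:04d}",
                    "insertion_frac": rng.random(),
                }
            )
            i += 1
    for _ in range(n_intergenic):
        rows.append({"barcode": barcodes[i], "gene_id": None, "insertion_frac": np.nan})
        i += 1
    return pd.DataFrame(rows)
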