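"""Insertion annotation, insertion-rate bias and essentiality candidates.

Each kept insertion is matched to the nearest gene and a feature class
(5' intergenic, 5' UTR, exon, intron, 3' UTR, 3' intergenic — the 5'/3'
sides reflect for minus-strand genes). Per-gene insertion density over
the CDS span (start codon to stop codon, introns included) feeds the
essentiality call: genes with fewer than 2 inserts/kb are candidates.
For bias analysis the whole genome is partitioned into feature classes
(promoter and terminator flanks included) and an observed-count-matched
null is resampled without replacement from each class.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneModel, PoolEntry

logger = logging.getLogger(__name__)

INSERTION_CLASSES = ("intergenic5", "utr5", "exon", "intron", "utr3", "intergenic3")

# whole-genome partition codes (promoter/terminator are fixed flanks)
PARTITION_CLASSES = (
    "promoter",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "terminator",
    "intergenic",
)
_CODE = {name: i for i, name in enumerate(PARTITION_CLASSES)}


@dataclass
class AnnotatedInsertion:
    barcode: str
    scaffold: str
    position: int
    strand: str
    nearest_gene_id: str | None
    feature_class: str
    distance_to_gene: int


class GeneIndex:
    """Genes grouped by scaffold and sorted by transcript start."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self.by_scaffold: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_scaffold.setdefault(g.scaffold, []).append(g)
        for lst in self.by_scaffold.values():
            lst.sort(key=lambda g: (g.tx_start, g.gene_id))
        self._starts = {
            s: [g.tx_start for g in lst] for s, lst in self.by_scaffold.items()
        }

    def candidates(self, scaffold: str, position: int, window: int = 3) -> list[GeneModel]:
        genes = self.by_scaffold.get(scaffold, [])
        if not genes:
            return []
        i = bisect_left(self._starts[scaffold], position)
        return genes[max(0, i - window) : i + window]


def _distance_to_span(position: int, start: int, end: int) -> int:
    if position < start:
        return start - position
    if position >= end:
        return position - end + 1
    return 0


def classify_insertion(
    scaffold: str, position: int, index: GeneIndex
) -> tuple[str | None, str, int]:
    """Nearest gene, feature class and distance for one genomic position.

    Inside a gene the class follows interval membership (CDS-overlapping
    exon bases are 'exon'); outside, 5' vs 3' intergenic follows which
    gene end is nearer, reflected by the gene's strand. Equidistant
    two-gene ties break toward the smaller gene_id (logged).
    """
    candidates = index.candidates(scaffold, position)
    if not candidates:
        return None, "intergenic5", -1
    scored = sorted(
        (
            (_distance_to_span(position, g.tx_start, g.tx_end), g.gene_id, g)
            for g in candidates
        ),
    )
    dist, _, gene = scored[0]
    if len(scored) > 1 and scored[1][0] == dist:
        logger.debug(
            "insertion %s:%d equidistant to %s and %s; keeping %s",
            scaffold,
            position,
            scored[0][1],
            scored[1][1],
            scored[0][1],
        )
    if dist == 0:
        return gene.gene_id, gene.feature_at(position), 0
    upstream = position < gene.tx_start
    if (upstream and gene.strand == "+") or (not upstream and gene.strand == "-"):
        return gene.gene_id, "intergenic5", dist
    return gene.gene_id, "intergenic3", dist


def annotate_pool(
    pool: list[PoolEntry], genes: list[GeneModel]
) -> pd.DataFrame:
    """Annotate kept pool entries with nearest gene and feature class."""
    index = GeneIndex(genes)
    rows = []
    for e in pool:
        if e.status != "kept":
            continue
        gene_id, feature, dist = classify_insertion(e.scaffold, e.position, index)
        rows.append(
            {
                "barcode": e.barcode,
                "scaffold": e.scaffold,
                "position": e.position,
                "strand": e.strand,
                "nearest_gene_id": gene_id,
                "feature_class": feature,
                "distance_to_gene": dist,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "scaffold",
            "position",
            "strand",
            "nearest_gene_id",
            "feature_class",
            "distance_to_gene",
        ],
    )


# ---------------------------------------------------------------------------
# Insertion density and essentiality


def gene_insert_density(
    pool: list[PoolEntry], genes: list[GeneModel]
) -> pd.DataFrame:
    """Kept insertions per kb of CDS span (start codon to stop codon)."""
    positions: dict[str, np.ndarray] = {}
    for scaffold in {g.scaffold for g in genes}:
        pos = sorted(
            e.position for e in pool if e.status == "kept" and e.scaffold == scaffold
        )
        positions[scaffold] = np.asarray(pos, dtype=np.int64)
    rows = []
    for g in genes:
        span = g.cds_end - g.cds_start
        if span <= 0:
            logger.warning("gene %s has zero-length CDS span; skipped", g.gene_id)
            continue
        pos = positions.get(g.scaffold, np.empty(0, dtype=np.int64))
        n = int(
            np.searchsorted(pos, g.cds_end, side="left")
            - np.searchsorted(pos, g.cds_start, side="left")
        )
        kb = span / 1000.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_inserts_cds": n,
                "cds_span_kb": kb,
                "density": n / kb,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_inserts_cds", "cds_span_kb", "density"])


def call_essential_candidates(
    density_table: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Flag genes with insertion density strictly below the threshold."""
    out = density_table.copy()
    out["essential_candidate"] = out["density"] < threshold
    return out


def density_histogram(
    density_table: pd.DataFrame, bin_width: float = 1.0
) -> pd.DataFrame:
    """Histogram of per-gene insertion densities (bin width in inserts/kb)."""
    dens = density_table["density"].to_numpy()
    n_bins = int(np.floor(dens.max() / bin_width)) + 1 if len(dens) else 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(dens, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": counts}
    )


# ---------------------------------------------------------------------------
# Local GC and feature partition


def local_gc(
    genome: dict[str, str], scaffold: str, position: int, window: int = 101
) -> float:
    """GC fraction in a centred window, truncated at scaffold ends.

    N bases are excluded from the denominator; an all-N window yields
    NaN (reported as missing).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = genome[scaffold]
    if not (0 <= position < len(seq)):
        raise ValueError(f"position {position} outside {scaffold}")
    half = window // 2
    sub = seq[max(0, position - half) : position + half + 1]
    gc = sum(sub.count(b) for b in "GC")
    acgt = sum(sub.count(b) for b in "ACGT")
    return gc / acgt if acgt else float("nan")


def build_feature_partition(
    genes: list[GeneModel],
    scaffold_lengths: dict[str, int],
    flank: int = 500,
) -> dict[str, np.ndarray]:
    """Assign every genomic base to exactly one feature class.

    Gene bodies take precedence (exon > UTR > intron within a gene;
    between overlapping genes, the earlier-starting gene wins). Promoter
    and terminator flanks (strand-aware, ``flank`` bases) fill remaining
    bases, truncated at neighbouring genes; where two flanks compete the
    base goes to the gene with the nearer transcript end. Everything
    else is intergenic.
    """
    code = {s: np.full(n, _CODE["intergenic"], dtype=np.uint8) for s, n in scaffold_lengths.items()}
    claimed = {s: np.zeros(n, dtype=bool) for s, n in scaffold_lengths.items()}

    for g in sorted(genes, key=lambda g: (g.scaffold, g.tx_start, g.gene_id)):
        arr = code[g.scaffold]
        taken = claimed[g.scaffold]
        span = slice(g.tx_start, g.tx_end)
        free = ~taken[span]
        body = np.full(g.tx_end - g.tx_start, _CODE["intron"], dtype=np.uint8)
        for a, b in g.exons:
            ca, cb = max(a, g.cds_start), min(b, g.cds_end)
            if ca < cb:
                body[ca - g.tx_start : cb - g.tx_start] = _CODE["exon"]
            if a < g.cds_start:
                side = "utr5" if g.strand == "+" else "utr3"
                body[a - g.tx_start : min(b, g.cds_start) - g.tx_start] = _CODE[side]
            if b > g.cds_end:
                side = "utr3" if g.strand == "+" else "utr5"
                body[max(a, g.cds_end) - g.tx_start : b - g.tx_start] = _CODE[side]
        arr[span][free] = body[free]  # arr[span] is a view; writes through
        taken[span] = True

    # flanks: nearer transcript end wins among competing flanks
    dist = {s: np.full(n, np.iinfo(np.int64).max, dtype=np.int64) for s, n in scaffold_lengths.items()}
    for g in genes:
        arr = code[g.scaffold]
        taken = claimed[g.scaffold]
        d = dist[g.scaffold]
        n = len(arr)
        upstream = (max(0, g.tx_start - flank), g.tx_start)
        downstream = (g.tx_end, min(n, g.tx_end + flank))
        for (a, b), label, anchor in (
            (upstream, "promoter" if g.strand == "+" else "terminator", g.tx_start),
            (downstream, "terminator" if g.strand == "+" else "promoter", g.tx_end - 1),
        ):
            if a >= b:
                continue
            idx = np.arange(a, b)
            cand = np.abs(idx - anchor)
            mask = (~taken[a:b]) & (cand < d[a:b])
            arr[a:b][mask] = _CODE[label]
            d[a:b][mask] = cand[mask]
    return code


def feature_insertion_rates(
    pool: list[PoolEntry],
    partition: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Observed insertions and rates (per kb) per feature class."""
    n_bases = {name: 0 for name in PARTITION_CLASSES}
    for arr in partition.values():
        counts = np.bincount(arr, minlength=len(PARTITION_CLASSES))
        for name, i in _CODE.items():
            n_bases[name] += int(counts[i])
    n_ins = {name: 0 for name in PARTITION_CLASSES}
    for e in pool:
        if e.status != "kept":
            continue
        cls = PARTITION_CLASSES[partition[e.scaffold][e.position]]
        n_ins[cls] += 1
    rows = []
    for name in PARTITION_CLASSES:
        kb = n_bases[name] / 1000.0
        rows.append(
            {
                "feature_class": name,
                "n_bases": n_bases[name],
                "n_insertions": n_ins[name],
                "inserts_per_kb": n_ins[name] / kb if kb else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def resample_feature_null(
    partition: dict[str, np.ndarray],
    observed_counts: dict[str, int],
    seed: int,
) -> dict[str, list[tuple[str, int]]]:
    """Count-matched null insertion positions per feature class.

    For each class, draws the observed number of positions uniformly
    without replacement from all genomic bases assigned to that class.
    Reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    scaffolds = sorted(partition)
    arrays = [partition[s] for s in scaffolds]
    offsets = np.cumsum([0] + [len(a) for a in arrays])
    flat = np.concatenate(arrays) if arrays else np.empty(0, dtype=np.uint8)
    out: dict[str, list[tuple[str, int]]] = {}
    for name, count in sorted(observed_counts.items()):
        pool_positions = np.flatnonzero(flat == _CODE[name])
        if count > len(pool_positions):
            raise ValueError(
                f"cannot sample {count} positions from {len(pool_positions)} "
                f"bases of class {name}"
            )
        chosen = rng.choice(pool_positions, size=count, replace=False)
        sampled = []
        for p in sorted(chosen.tolist()):
            i = np.searchsorted(offsets, p, side="right") - 1
            sampled.append((scaffolds[i], int(p - offsets[i])))
        out[name] = sampled
    return out
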