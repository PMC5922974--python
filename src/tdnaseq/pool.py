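"""Filter cascade that turns per-barcode TnSeq tallies into a mutant pool.

Five rules are applied in a fixed order, each over the barcodes that
survived the previous rules:

1. off-by-one  — a barcode one edit away from a barcode with >= 100x
   more reads is a likely sequencing error;
2. past-end    — more than 7x as many past-end reads as genomic reads
   marks a concatemer or unprocessed-vector junction, subtyped as
   head-to-tail (left border majority), head-to-head (right border
   majority) or run-on (vector majority);
3. ambiguous   — a strict majority of reads mapping ambiguously;
4. multilocus  — >= 20% of genomic reads at a location other than the
   most commonly observed one;
5. off-by-two  — mapped within 10 bases of a more abundant barcode at
   Levenshtein distance < 5.

Ratio readings are literal: ">= 100x", "strictly > 7x", ">= 20%",
"< 5", "majority" = strictly more than half; all are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .models import PoolEntry
from .tnseq import BarcodeTally

logger = logging.getLogger(__name__)

try:  # fast path; the DP below is the required built-in fallback
    import edlib

    def levenshtein(a: str, b: str) -> int:
        """Unit-cost edit distance between two strings."""
        if not a or not b:
            return max(len(a), len(b))
        return edlib.align(a, b, task="distance")["editDistance"]

except ImportError:  # pragma: no cover - exercised where edlib is absent

    def levenshtein(a: str, b: str) -> int:
        """Unit-cost edit distance between two strings."""
        return levenshtein_dp(a, b)


def levenshtein_dp(a: str, b: str) -> int:
    """Classic O(len(a)*len(b)) dynamic-programming edit distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _within_distance_one(a: str, b: str, include_indels: bool = True) -> bool:
    """True when the strings differ by one substitution or (optionally)
    one insertion/deletion — the neighbourhood relevant for off-by-one
    sequencing errors on variable-length barcodes."""
    la, lb = len(a), len(b)
    if la == lb:
        diff = 0
        for x, y in zip(a, b):
            if x != y:
                diff += 1
                if diff > 1:
                    return False
        return diff == 1
    if not include_indels or abs(la - lb) != 1:
        return False
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


@dataclass
class FilterReport:
    """Outcome of the filter cascade: statuses partition the barcodes."""

    assignments: dict[str, str] = field(default_factory=dict)
    rules: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for status in self.assignments.values():
            out[status] = out.get(status, 0) + 1
        return out


Tallies = Mapping[str, BarcodeTally]


def filter_off_by_one(
    tallies: Tallies, ratio: float = 100.0, include_indels: bool = True
) -> set[str]:
    """Barcodes one edit from a barcode with >= ratio times more reads."""
    removed: set[str] = set()
    items = [(bc, t.total_reads) for bc, t in tallies.items()]
    by_reads = sorted(items, key=lambda kv: -kv[1])
    for bc, reads in items:
        for other, other_reads in by_reads:
            if other_reads < ratio * reads:
                break
            if other != bc and _within_distance_one(bc, other, include_indels):
                removed.add(bc)
                break
    return removed


def classify_past_end(tallies: Tallies, ratio: float = 7.0) -> dict[str, str]:
    """Barcodes with strictly more than ``ratio`` x past-end vs genomic reads.

    The subtype follows the majority past-end evidence; ties are broken
    in the fixed order head-to-tail > head-to-head > run-on and logged.
    """
    flagged: dict[str, str] = {}
    for bc, t in tallies.items():
        if t.n_pastend > ratio * t.n_genomic:
            counts = [
                (t.n_pastend_left, "past_end_head_to_tail"),
                (t.n_pastend_right, "past_end_head_to_head"),
                (t.n_pastend_vector, "past_end_run_on"),
            ]
            best = max(n for n, _ in counts)
            winners = [label for n, label in counts if n == best]
            if len(winners) > 1:
                logger.info(
                    "past-end subtype tie for %s: %s -> %s", bc, winners, winners[0]
                )
            flagged[bc] = winners[0]
    return flagged


def filter_ambiguous(tallies: Tallies) -> set[str]:
    """Barcodes whose reads map ambiguously in the strict majority."""
    return {
        bc for bc, t in tallies.items() if t.n_ambiguous * 2 > t.total_reads
    }


def filter_multilocus(tallies: Tallies, fraction: float = 0.20) -> set[str]:
    """Barcodes with >= ``fraction`` of genomic reads off the mode location.

    Barcodes with no genomic reads are not evaluated by this rule.
    """
    removed: set[str] = set()
    for bc, t in tallies.items():
        total = t.n_genomic
        if total == 0:
            continue
        off_mode = total - t.mode_location.n_reads
        if off_mode >= fraction * total:
            removed.add(bc)
    return removed


def filter_off_by_two(
    tallies: Tallies, max_position_delta: int = 10, max_edit_distance: int = 5
) -> set[str]:
    """Barcodes near a more abundant barcode with a similar sequence.

    Removed iff a strictly more abundant barcode maps within
    ``max_position_delta`` bases on the same scaffold and the edit
    distance is strictly below ``max_edit_distance``.
    """
    located = [
        (bc, t.total_reads, t.mode_location)
        for bc, t in tallies.items()
        if t.mode_location is not None
    ]
    by_scaffold: dict[str, list] = {}
    for bc, reads, loc in located:
        by_scaffold.setdefault(loc.scaffold, []).append((loc.position, reads, bc))
    removed: set[str] = set()
    for scaffold, rows in by_scaffold.items():
        rows.sort()
        for i, (pos, reads, bc) in enumerate(rows):
            for j in range(i + 1, len(rows)):
                pos2, reads2, bc2 = rows[j]
                if pos2 - pos > max_position_delta:
                    break
                if levenshtein(bc, bc2) < max_edit_distance:
                    if reads2 > reads:
                        removed.add(bc)
                    elif reads > reads2:
                        removed.add(bc2)
    return removed


def build_pool(
    tallies: Tallies,
    off_by_one_ratio: float = 100.0,
    past_end_ratio: float = 7.0,
    multilocus_fraction: float = 0.20,
    off_by_two_position: int = 10,
    off_by_two_edit: int = 5,
    include_indels: bool = True,
) -> tuple[list[PoolEntry], FilterReport]:
    """Apply the five filters in order and emit the mutant pool.

    Each rule sees only the barcodes that survived the previous rules,
    so the cascade equals the sequential composition of the single-rule
    operations. Surviving barcodes with no genomic location (reads all
    unmapped) cannot be placed and are excluded from the pool; they are
    counted in the report under 'unplaced'.
    """
    report = FilterReport()
    surviving = dict(tallies)

    def apply(removals: Mapping[str, str] | set[str], label: str | None, rule: str):
        report.rules.append(rule)
        if isinstance(removals, set):
            removals = {bc: label for bc in removals}
        for bc, status in removals.items():
            report.assignments[bc] = status
            surviving.pop(bc, None)

    apply(
        filter_off_by_one(surviving, off_by_one_ratio, include_indels),
        "off_by_one",
        "off_by_one",
    )
    apply(classify_past_end(surviving, past_end_ratio), None, "past_end")
    apply(filter_ambiguous(surviving), "ambiguous", "ambiguous")
    apply(filter_multilocus(surviving, multilocus_fraction), "multilocus", "multilocus")
    apply(
        filter_off_by_two(surviving, off_by_two_position, off_by_two_edit),
        "off_by_two",
        "off_by_two",
    )

    entries: list[PoolEntry] = []
    for bc in sorted(surviving):
        t = surviving[bc]
        loc = t.mode_location
        if loc is None:
            report.assignments[bc] = "unplaced"
            continue
        report.assignments[bc] = "kept"
        entries.append(
            PoolEntry(
                barcode=bc,
                scaffold=loc.scaffold,
                position=loc.position,
                strand=loc.strand,
                n_genomic_reads=t.n_genomic,
                n_pastend_reads=t.n_pastend,
                status="kept",
            )
        )
    logger.info("pool built: %s", report.counts)
    return entries, report
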